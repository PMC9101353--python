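"""Estimation of the bundle's mechanical parameters from measurements.

Covers the full inference chain: weighted linear fits of the short/long
time radius-versus-strain response, exponential relaxation times,
recruitment kinetics (alpha, t*), least-squares fitting of the local
tension ODE to normalized intensity traces, and the arithmetic that maps
the fitted slopes to physical constants (cortical tension, line tension,
spring constants, the rigidity-to-surface-tension length l_f).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .exceptions import (
    IdentifiabilityWarning,
    InvalidParameterError,
    ModelValidityError,
    NumericalError,
    SfmechWarning,
)
from .localode import LocalOdeParams, simulate_local_chi

__all__ = [
    "FitResult",
    "fit_linear_strain_response",
    "fit_exponential_relax",
    "fit_recruitment",
    "fit_local_ode",
    "derived_mechanics",
    "DEFAULT_LOCAL_BOUNDS",
]


@dataclass
class FitResult:
    """Named estimates with uncertainties and fit diagnostics."""

    estimates: dict
    sd: dict
    residual_norm: float
    n: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.estimates) - set(self.sd)
        for name in missing:
            self.sd[name] = float("nan")

    def __getitem__(self, name):
        return self.estimates[name]

    def as_dict(self):
        """JSON-ready record (non-serializable diagnostics dropped)."""
        import json

        def safe(v):
            try:
                json.dumps(v)
                return True
            except (TypeError, ValueError):
                return False

        return {
            "estimates": self.estimates,
            "sd": self.sd,
            "residual_norm": self.residual_norm,
            "n": self.n,
            "converged": self.converged,
            "diagnostics": {k: v for k, v in self.diagnostics.items() if safe(v)},
        }

    def to_json(self, path):
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.as_dict(), indent=1, default=float))


def _wls_line(x, y, w):
    """Weighted least-squares line fit; returns (slope, intercept, cov)."""
    X = np.column_stack([x, np.ones_like(x)])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    if np.linalg.cond(xtwx) > 1e12:
        raise NumericalError("singular design: strain values are not distinct")
    cov = np.linalg.inv(xtwx)
    beta = cov @ X.T @ W @ y
    return beta[0], beta[1], cov


def fit_linear_strain_response(eps, y, errors=None):
    """Weighted linear fit of a response (um) against applied strain.

    ``errors`` are per-point standard deviations; when given, the
    covariance is the textbook known-variance form, otherwise it is scaled
    by the residual variance.  Two points give exact interpolation with
    undefined uncertainties (flagged in diagnostics).
    """
    eps = np.asarray(eps, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(eps) != len(y) or len(eps) < 2:
        raise InvalidParameterError("need >= 2 (eps, y) pairs of equal length")
    if len(np.unique(eps)) < 2:
        raise NumericalError("singular design: all strain values identical")
    w = np.ones_like(y) if errors is None else 1.0 / np.asarray(errors, float) ** 2
    slope, intercept, cov = _wls_line(eps, y, w)
    resid = y - (slope * eps + intercept)
    rss = float(np.sum(w * resid**2))
    n = len(y)
    diagnostics = {}
    if n == 2:
        sd_slope = sd_int = float("nan")
        diagnostics["exact_interpolation"] = True
    else:
        scale = 1.0 if errors is not None else rss / (n - 2)
        sd_slope = float(np.sqrt(scale * cov[0, 0]))
        sd_int = float(np.sqrt(scale * cov[1, 1]))
    return FitResult(
        estimates={"slope": float(slope), "intercept": float(intercept)},
        sd={"slope": sd_slope, "intercept": sd_int},
        residual_norm=rss,
        n=n,
        converged=True,
        diagnostics=diagnostics,
    )


def _exp_decay(t, y_inf, y0, T):
    return y_inf + (y0 - y_inf) * np.exp(-t / T)


def _overshoot(t, a, T_slow, q):
    # difference of exponentials with T_fast = q * T_slow, q in (0, 1)
    return a * (np.exp(-t / T_slow) - np.exp(-t / (q * T_slow)))


def fit_exponential_relax(t, y, kind="decay_to_plateau"):
    """Fit an exponential relaxation; returns amplitude/timescale/plateau.

    ``kind='decay_to_plateau'`` fits ``y_inf + (y0 - y_inf)*exp(-t/T)``;
    ``kind='overshoot'`` fits a difference of exponentials
    ``a*(exp(-t/T1) - exp(-t/T2))`` with ``T1 > T2`` and reports the slow
    scale ``T1`` as ``timescale``.  Multi-start over the timescale; a data
    span shorter than two fitted timescales triggers a warning.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise InvalidParameterError("t and y must have equal length")
    if len(t) < 10:
        warnings.warn("fewer than 10 samples: relaxation fit is unreliable",
                      SfmechWarning, stacklevel=2)
    span = t[-1] - t[0]
    if span <= 0:
        raise InvalidParameterError("t must span a positive interval")
    t_starts = span * np.array([0.03, 0.1, 0.3, 1.0])

    best = None
    if kind == "decay_to_plateau":
        def resid(p):
            return _exp_decay(t, *p) - y
        for T0 in t_starts:
            p0 = [y[-1], y[0], T0]
            sol = least_squares(
                resid, p0,
                bounds=([-np.inf, -np.inf, span * 1e-4], [np.inf, np.inf, span * 10.0]),
                xtol=1e-12, ftol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        y_inf, y0, T = best.x
        estimates = {
            "amplitude": float(y0 - y_inf),
            "timescale": float(T),
            "plateau": float(y_inf),
        }
    elif kind == "overshoot":
        def resid(p):
            return _overshoot(t, *p) - y
        peak = y[np.argmax(np.abs(y))]
        for T0 in t_starts:
            for q0 in (0.1, 0.4):
                p0 = [peak if peak != 0 else 1.0, T0, q0]
                sol = least_squares(
                    resid, p0,
                    bounds=([-np.inf, span * 1e-4, 1e-3], [np.inf, span * 10.0, 0.999]),
                    xtol=1e-12, ftol=1e-12,
                )
                if best is None or sol.cost < best.cost:
                    best = sol
        a, T_slow, q = best.x
        estimates = {
            "amplitude": float(a),
            "timescale": float(T_slow),
            "timescale_fast": float(q * T_slow),
            "plateau": 0.0,
        }
    else:
        raise InvalidParameterError(f"unknown kind {kind!r}")

    converged = bool(best.success)
    if span < 2.0 * estimates["timescale"]:
        warnings.warn(
            f"data span {span:.3g} s covers less than two fitted timescales "
            f"({estimates['timescale']:.3g} s)",
            SfmechWarning, stacklevel=2,
        )
    sd = _covariance_sd(best, list(estimates))
    return FitResult(
        estimates=estimates,
        sd=sd,
        residual_norm=float(2.0 * best.cost),
        n=len(y),
        converged=converged,
        diagnostics={"kind": kind},
    )


def _covariance_sd(sol, names):
    """Standard deviations from a least_squares solution's Jacobian."""
    n, p = sol.jac.shape
    sd = {name: float("nan") for name in names}
    if n <= p:
        return sd
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * (2.0 * sol.cost / (n - p))
    except np.linalg.LinAlgError:
        return sd
    diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    for i, name in enumerate(names[: len(diag)]):
        sd[name] = float(diag[i])
    return sd


def fit_recruitment(eps_list, plateau_list, init_slope_list):
    """Recruitment index and time scale from strain-resolved intensities.

    ``alpha`` is the through-origin regression slope of the intensity
    plateau ``(Delta I/I0)_inf`` on strain; the recruitment rate
    ``alpha/t*`` the same regression of the initial intensity slope; and
    ``t* = alpha / (alpha/t*)``.
    """
    eps = np.asarray(eps_list, dtype=float)
    plateau = np.asarray(plateau_list, dtype=float)
    slope0 = np.asarray(init_slope_list, dtype=float)
    if not (len(eps) == len(plateau) == len(slope0)):
        raise InvalidParameterError("inputs must have equal length")
    if len(np.unique(eps)) < 3:
        raise InvalidParameterError("need >= 3 distinct strain levels")

    def through_origin(x, y):
        sxx = float(np.sum(x * x))
        b = float(np.sum(x * y)) / sxx
        resid = y - b * x
        n = len(y)
        var_b = float(np.sum(resid**2)) / max(n - 1, 1) / sxx
        return b, np.sqrt(var_b)

    alpha, sd_alpha = through_origin(eps, plateau)
    rate, sd_rate = through_origin(eps, slope0)
    if rate <= 0:
        raise NumericalError(f"fitted recruitment rate alpha/t* = {rate:.3g} <= 0")
    t_star = alpha / rate
    sd_t = t_star * np.hypot(sd_alpha / alpha if alpha else 0.0, sd_rate / rate)
    rss = float(np.sum((plateau - alpha * eps) ** 2) + np.sum((slope0 - rate * eps) ** 2))
    return FitResult(
        estimates={"alpha": alpha, "rate": rate, "t_star": float(t_star)},
        sd={"alpha": float(sd_alpha), "rate": float(sd_rate), "t_star": float(sd_t)},
        residual_norm=rss,
        n=len(eps),
        converged=True,
        diagnostics={},
    )


# -- local ODE fit -----------------------------------------------------------

#: default box: nu^-1 in [50, 2000] s, tau in [50, 1000] s, f, Gamma bounded
DEFAULT_LOCAL_BOUNDS = {
    "nu": (1.0 / 2000.0, 1.0 / 50.0),
    "tau": (50.0, 1000.0),
    "f": (0.1, 20.0),
    "Gamma": (0.05, 5.0),
}


def _simulate_xi(theta, t, xi0, xidot0):
    nu, tau, f, Gamma = theta
    p = LocalOdeParams(nu=nu, tau=tau, f=f, Gamma=Gamma)
    chi0 = tau * xi0
    chidot0 = tau * xidot0
    # fit-loop tolerance: well below the noise floor, far above solver cost
    trace = simulate_local_chi(p, chi0=chi0, chidot0=chidot0, t_grid=t,
                               form="second", rtol=1e-7, atol=1e-9,
                               cap_step=False, max_rhs_evals=20000)
    return trace.xi


def fit_local_ode(
    trace,
    t=None,
    dt=None,
    mapping=1.0,
    init=None,
    bounds=None,
    K0=0.19,
    eps_l=0.2,
    R0=65.6,
    smooth_window=11,
):
    """Least-squares fit of the local tension ODE to an intensity trace.

    ``trace`` is the normalized relative intensity of one segment,
    proportional to ``xi`` through ``mapping`` (default 1, the measured
    intensity-tension proportionality).  Initial conditions ``(chi0,
    chidot0)`` come from local-quadratic (Savitzky-Golay) smoothed values
    and derivatives of the trace, scaled by the candidate ``tau``; the
    second-order ODE form is integrated.  A structured multi-start (a
    log-spaced grid over ``bounds`` plus the physics-informed ``init``) is
    screened, the best starts are refined, and residual near-ties break
    toward ``init`` — the fit is anchored at the static-analysis parameter
    values in the flat-ridge regime of weak motor nonlinearity, and the
    ``Gamma*nu*tau`` identity is reported as a diagnostic, never enforced.

    Fitted ``f`` maps back to physical anchors via ``sigma0 =
    K0*eps_l/(2f)`` and ``lambda0 = sigma0*R0``.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1 or len(y) < 50:
        raise InvalidParameterError("trace must be 1-D with >= 50 samples")
    if t is None:
        if dt is None:
            raise InvalidParameterError("provide t or dt")
        t = dt * np.arange(len(y))
    t = np.asarray(t, dtype=float)
    dt = float(t[1] - t[0])
    box = dict(DEFAULT_LOCAL_BOUNDS)
    if bounds:
        box.update(bounds)

    xi_data = y / mapping
    window = min(smooth_window, len(y) - (1 - len(y) % 2))
    window = max(window if window % 2 == 1 else window - 1, 5)
    xi_smooth = savgol_filter(xi_data, window, 2)
    xi_deriv = savgol_filter(xi_data, window, 2, deriv=1, delta=dt)
    # smoothed value/derivative start the initial conditions, which are
    # co-estimated: the second-order form amplifies any fixed IC error
    # exponentially, so (xi0, xidot0) enter the fit as nuisance parameters
    xi0_guess, xidot0_guess = float(xi_smooth[0]), float(xi_deriv[0])

    # degenerate flat trace: no tension dynamics to fit
    if np.ptp(xi_data) < 1e-9 * max(1.0, np.max(np.abs(xi_data))):
        warnings.warn("flat trace: f ~ 0 and remaining parameters are "
                      "unidentifiable", IdentifiabilityWarning, stacklevel=2)
        nan = float("nan")
        return FitResult(
            estimates={"nu": nan, "tau": nan, "f": 0.0, "Gamma": nan,
                       "sigma0": nan, "lambda0": nan},
            sd={},
            residual_norm=0.0,
            n=len(y),
            converged=True,
            diagnostics={"unidentifiable": ["nu", "tau", "Gamma"],
                         "gamma_nu_tau": nan},
        )

    # nuisance IC bounds: generous around the observed trace
    spread = float(np.ptp(xi_data)) + 1e-6
    ic_lo = np.array([xi_data.min() - spread, -10.0 * (abs(xidot0_guess) + spread / dt)])
    ic_hi = np.array([xi_data.max() + spread, +10.0 * (abs(xidot0_guess) + spread / dt)])
    ic0 = np.clip([xi0_guess, xidot0_guess], ic_lo, ic_hi)

    def residuals(theta):
        try:
            xi_model = _simulate_xi(theta[:4], t, theta[4], theta[5])
        except (NumericalError, InvalidParameterError):
            return np.full(len(y), 1e6)
        return xi_model * mapping - y

    names = ("nu", "tau", "f", "Gamma")
    lo = np.concatenate([[box[k][0] for k in names], ic_lo])
    hi = np.concatenate([[box[k][1] for k in names], ic_hi])

    starts = []
    if init is not None:
        starts.append(np.clip(
            np.concatenate([[init.nu, init.tau, init.f, init.Gamma], ic0]),
            lo, hi))
    grid_axes = [np.geomspace(box[k][0], box[k][1], 3) for k in names]
    mesh = np.stack(np.meshgrid(*grid_axes, indexing="ij"), axis=-1).reshape(-1, 4)
    starts.extend(np.concatenate([m, ic0]) for m in mesh)

    costs = np.array([float(np.sum(residuals(th) ** 2)) for th in starts])
    order = np.argsort(costs)
    refine_idx = list(order[:2])
    if init is not None and 0 not in refine_idx:
        refine_idx.append(0)

    solutions = []
    for i in refine_idx:
        sol = least_squares(
            residuals, starts[i], bounds=(lo, hi),
            xtol=1e-10, ftol=1e-10, max_nfev=100, diff_step=1e-4,
        )
        solutions.append(sol)
    best = min(solutions, key=lambda s: s.cost)
    # polish the winner to full convergence
    best = least_squares(residuals, best.x, bounds=(lo, hi),
                         xtol=1e-12, ftol=1e-12, max_nfev=300, diff_step=1e-6)

    # f is identified by the Gaussian motor nonlinearity alone, which is
    # quartic in the (small) rate chi_dot: on weakly nonlinear traces the
    # objective has a flat ridge trading f against Gamma*tau.  The procedure
    # then constrains f to the static-analysis anchor (the initializer) and
    # refits the identifiable (nu, tau, Gamma); the constraint is adopted
    # only if the data cannot reject it (residual within 2% of the free fit).
    ridge_flat = False
    if init is not None:
        f_anchor = float(np.clip(init.f, box["f"][0], box["f"][1]))

        def residuals5(theta5):
            return residuals([theta5[0], theta5[1], f_anchor, theta5[2],
                              theta5[3], theta5[4]])

        keep = [0, 1, 3, 4, 5]
        lo5, hi5 = lo[keep], hi[keep]
        starts5 = [np.clip(best.x[keep], lo5, hi5),
                   np.clip(np.concatenate(
                       [[init.nu, init.tau, init.Gamma], ic0]), lo5, hi5)]
        sols5 = [least_squares(residuals5, s5, bounds=(lo5, hi5),
                               xtol=1e-9, ftol=1e-9, max_nfev=150,
                               diff_step=1e-4)
                 for s5 in starts5]
        best5 = min(sols5, key=lambda s: s.cost)
        if best5.cost <= best.cost * 1.02:
            ridge_flat = True
            warnings.warn(
                "f is not identified by this trace (flat ridge); constrained "
                "to the static-analysis anchor", IdentifiabilityWarning,
                stacklevel=2)
            best = best5

    if ridge_flat:
        nu, tau, Gamma = best.x[:3]
        f = f_anchor
        names = ("nu", "tau", "Gamma", "xi0", "xidot0")
        lo_b, hi_b = lo5, hi5
    else:
        nu, tau, f, Gamma = best.x[:4]
        names = ("nu", "tau", "f", "Gamma", "xi0", "xidot0")
        lo_b, hi_b = lo, hi
    sigma0 = K0 * eps_l / (2.0 * f)
    lambda0 = sigma0 * R0
    sd = _covariance_sd(best, list(names))
    sd["sigma0"] = sigma0 / f * sd.get("f", float("nan"))
    sd["lambda0"] = sd["sigma0"] * R0
    on_bounds = [names[i] for i in range(len(best.x))
                 if np.isclose(best.x[i], lo_b[i]) or np.isclose(best.x[i], hi_b[i])]
    converged = bool(best.success) and not np.any(np.isnan(best.x))
    return FitResult(
        estimates={
            "nu": float(nu), "tau": float(tau), "f": float(f),
            "Gamma": float(Gamma), "sigma0": float(sigma0),
            "lambda0": float(lambda0),
        },
        sd=sd,
        residual_norm=float(2.0 * best.cost),
        n=len(y),
        converged=converged,
        diagnostics={
            "gamma_nu_tau": float(Gamma * nu * tau),
            "bounds_hit": on_bounds,
            "ridge_flat": ridge_flat,
            "f_constrained": ridge_flat,
            "nu_inv_s": float(1.0 / nu),
            "xi0": float(best.x[-2]),
            "xidot0": float(best.x[-1]),
            "mapping": mapping,
        },
    )


def derived_mechanics(short_slope, long_slope, E, A, L0, R0):
    """Physical constants from the two radius-versus-strain slopes.

    The short-time (elastic) slope equals ``K0*L0/sigma = E*A/sigma`` so
    ``sigma = E*A/short_slope``; the long-time slope is reduced by the
    series spring factor ``k/(k+K0)``, giving ``K0/k = short/long - 1``.
    Also returns ``lambda0 = sigma*R0``, ``K0 = E*A/L0``, ``k`` and the
    rigidity-to-surface-tension length ``l_f = E*A/sigma``.
    """
    for name, v in [("short_slope", short_slope), ("long_slope", long_slope),
                    ("E", E), ("A", A), ("L0", L0), ("R0", R0)]:
        if v <= 0:
            raise InvalidParameterError(f"{name} must be strictly positive")
    if long_slope >= short_slope:
        raise ModelValidityError(
            "long-time slope must be below the short-time slope "
            f"(got {long_slope} >= {short_slope}): the series spring factor "
            "k/(k+K0) is < 1"
        )
    EA = E * A
    sigma = EA / short_slope
    K0 = EA / L0
    K0_over_k = short_slope / long_slope - 1.0
    k = K0 / K0_over_k
    return FitResult(
        estimates={
            "sigma": sigma,                  # nN/um
            "sigma_pN_per_um": sigma * 1e3,  # display convention
            "lambda0": sigma * R0,           # nN
            "K0": K0,                        # nN/um
            "k": k,                          # nN/um
            "K0_over_k": K0_over_k,
            "lf": EA / sigma,                # um (== short_slope)
        },
        sd={},
        residual_norm=0.0,
        n=2,
        converged=True,
        diagnostics={"inputs": {"short_slope": short_slope,
                                "long_slope": long_slope,
                                "E": E, "A": A, "L0": L0, "R0": R0}},
    )
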