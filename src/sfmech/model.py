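"""Three-element active viscoelastic model of a peripheral stress fiber.

A peripheral stress fiber (SF) anchored at two focal adhesions is pulled
into a circular arc by the cell's cortical tension ``sigma``; the arc radius
satisfies the Bischofs balance ``R = lambda / sigma`` with ``lambda`` the
line tension along the bundle.  The bundle itself is modelled as a main
spring ``K`` in series with a parallel group of a secondary spring ``k``,
a dashpot ``gamma`` and an active motor element whose force-velocity law is
a Gaussian, ``F_M(v) = lambda0 * exp(-v**2 / V**2)``:

    K * delta1 + lambda0                                  = lambda
    k * delta2 + gamma * ddelta2 + F_M(ddelta2)           = lambda
    delta1 + delta2                                       = delta_l

``delta1`` and ``delta2`` are the elongations of the two branches and
``delta_l`` the total imposed elongation.  The Gaussian motor term makes
the rate equation implicit in ``ddelta2``; the integrator solves a scalar
root problem at every step with continuation from the previous rate.

Strain gating (the experimentally observed asymmetry): under compression
(``eps < 0``) the secondary spring disengages (``k = 0``, Maxwell branch)
and ``K = K0``; under extension fresh actin recruitment softens the main
spring, ``K(eps, t) = K0 * (1 - alpha*eps*(1 - exp(-t/t_star)))``, while the
bundle intensity gains ``Delta I / I0 = alpha*eps*(1 - exp(-t/t_star))``.

Units throughout: micrometres, seconds, nanonewtons (tensions in nN/um).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import (
    DomainWarning,
    IntegrationError,
    InvalidParameterError,
    ModelValidityError,
    MultiRootWarning,
    NumericalError,
    StrainRangeWarning,
)

__all__ = [
    "GlobalMechParams",
    "StretchProtocol",
    "BundleTrace",
    "motor_force",
    "solve_rate_implicit",
    "simulate_global",
    "radius_short_time",
    "radius_long_time",
    "radius_long_time_exact",
    "elastic_constant_t",
    "secondary_constant",
    "intensity_model",
    "density_variation",
    "elastic_reference",
]

#: strain magnitude beyond which a warning is emitted (explored range)
STRAIN_WARN_THRESHOLD = 0.4


@dataclass(frozen=True)
class GlobalMechParams:
    """Physical constants of the bundle.

    Parameters
    ----------
    K0 : float
        Main spring constant at zero strain (nN/um).
    k : float
        Secondary spring constant (nN/um); disengages under compression.
    gamma : float
        Dissipation constant of the motor/filament interaction (nN*s/um).
    lambda0 : float
        Unperturbed line tension and motor stall force (nN).
    V : float
        Motor velocity scale, width of the Gaussian force-velocity law (um/s).
    sigma : float
        Cortical tension (nN/um); display convention is pN/um (x1000).
    E : float
        Young's modulus of the bundle (nN/um^2).
    A : float
        Cross-sectional area (um^2).
    alpha : float
        Actin recruitment index (dimensionless).
    t_star : float
        Recruitment time scale (s).
    """

    K0: float
    k: float
    gamma: float
    lambda0: float
    V: float
    sigma: float
    E: float
    A: float
    alpha: float
    t_star: float

    def __post_init__(self):
        for name in ("K0", "gamma", "lambda0", "V", "sigma", "E", "A", "t_star"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise InvalidParameterError(
                    f"{name} must be strictly positive, got {value!r}"
                )
        if self.k < 0:
            raise InvalidParameterError(f"k must be >= 0, got {self.k!r}")
        if self.alpha < 0:
            raise InvalidParameterError(f"alpha must be >= 0, got {self.alpha!r}")

    @classmethod
    def from_modulus(cls, E, A, L0, *, k, gamma, lambda0, V, sigma, alpha, t_star):
        """Construct with ``K0 = E*A/L0`` (extensional spring of a rod)."""
        return cls(
            K0=E * A / L0, k=k, gamma=gamma, lambda0=lambda0, V=V,
            sigma=sigma, E=E, A=A, alpha=alpha, t_star=t_star,
        )

    @property
    def R0(self):
        """Unperturbed arc radius ``lambda0 / sigma`` (um)."""
        return self.lambda0 / self.sigma


@dataclass(frozen=True)
class StretchProtocol:
    """Imposed strain history: optional prestretch phase, then a step.

    ``epsilon`` is the signed strain of the main step, referenced to the
    unstretched bundle length ``L0`` (so a prestretch by ``+e`` followed by
    a step of ``-e`` returns the bundle exactly to rest length).  For
    compression experiments the bundle is first prestretched by
    ``prestretch_epsilon`` and held for ``prestretch_hold`` seconds; the
    radius response is then measured from the prestretched radius ``R0p``.
    Time zero is the start of the main ramp, which is applied as a linear
    ramp of duration ``|delta_step| / rate`` (near-instantaneous at the
    experimental rate of 100 um/s).
    """

    epsilon: float
    rate: float = 100.0
    L0: float = 36.47
    prestretch_epsilon: float = 0.0
    prestretch_hold: float = 0.0
    direction: str = "extension"

    def __post_init__(self):
        if self.direction not in ("extension", "compression"):
            raise InvalidParameterError(
                f"direction must be 'extension' or 'compression', got {self.direction!r}"
            )
        if self.rate <= 0 or self.L0 <= 0:
            raise InvalidParameterError("rate and L0 must be strictly positive")
        if self.prestretch_epsilon < 0:
            raise InvalidParameterError("prestretch_epsilon must be >= 0")
        if self.prestretch_hold < 0:
            raise InvalidParameterError("prestretch_hold must be >= 0")
        if self.direction == "compression":
            if not (self.prestretch_epsilon > 0 and self.epsilon < 0):
                raise InvalidParameterError(
                    "compression requires prestretch_epsilon > 0 and epsilon < 0"
                )
        if abs(self.epsilon) > STRAIN_WARN_THRESHOLD:
            warnings.warn(
                f"|epsilon| = {abs(self.epsilon):.3g} exceeds the explored "
                f"range {STRAIN_WARN_THRESHOLD}",
                StrainRangeWarning,
                stacklevel=2,
            )

    @property
    def step_elongation(self):
        """Signed total elongation of the main step (um)."""
        return self.epsilon * self.L0

    @property
    def ramp_duration(self):
        """Duration of the main linear ramp (s)."""
        return abs(self.step_elongation) / self.rate

    def delta_l(self, t):
        """Total imposed elongation (um) at time ``t >= 0`` (main phase)."""
        t = np.asarray(t, dtype=float)
        pre = self.prestretch_epsilon * self.L0
        tr = self.ramp_duration
        if tr == 0.0:
            frac = np.where(t >= 0.0, 1.0, 0.0)
        else:
            frac = np.clip(t / tr, 0.0, 1.0)
        return pre + self.step_elongation * frac


@dataclass
class BundleTrace:
    """Simulated time course of the bundle state.

    Invariants (checked in tests): ``delta1 + delta2 == delta_l``,
    ``lam == K_t * delta1 + lambda0`` and ``R == lam / sigma`` at every
    sample.
    """

    t: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    delta_l: np.ndarray
    lam: np.ndarray
    R: np.ndarray
    K_t: np.ndarray
    params: GlobalMechParams | None = None
    protocol: StretchProtocol | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "delta1_um": self.delta1,
                "delta2_um": self.delta2,
                "lambda_nN": self.lam,
                "R_um": self.R,
                "K_nN_per_um": self.K_t,
            }
        )

    def to_csv(self, path):
        self.as_frame().to_csv(path, index=False)


def motor_force(rate, lambda0, V):
    """Gaussian motor force-velocity law ``lambda0 * exp(-rate**2/V**2)``.

    Maximal (stall) force at zero elongation rate; even in the rate.
    """
    if V <= 0:
        raise InvalidParameterError(f"V must be strictly positive, got {V!r}")
    if lambda0 <= 0:
        raise InvalidParameterError(f"lambda0 must be strictly positive, got {lambda0!r}")
    rate = np.asarray(rate, dtype=float)
    out = lambda0 * np.exp(-(rate**2) / V**2)
    return float(out) if out.ndim == 0 else out


def _monotone_rate_equation(params: GlobalMechParams) -> bool:
    """True when ``g(x) = gamma*x + lambda0*exp(-x^2/V^2)`` is monotone.

    The Gaussian term's steepest descent is ``sqrt(2)*exp(-1/2)*lambda0/V``
    (at ``x = V/sqrt(2)``); below that dissipation level several rates can
    balance the same load.
    """
    return params.gamma >= math.sqrt(2.0) * math.exp(-0.5) * params.lambda0 / params.V


def solve_rate_implicit(delta2, delta_l, params, K_now, prev_rate=0.0, k_now=None):
    """Solve the implicit rate equation for ``ddelta2``.

    Finds ``x`` with ``gamma*x + lambda0*exp(-x^2/V^2) = RHS`` where
    ``RHS = K_now*(delta_l - delta2) + lambda0 - k_now*delta2`` (line
    tension balance of the motor branch).  In the non-monotone regime the
    root nearest ``prev_rate`` is returned and :class:`MultiRootWarning`
    is emitted when several roots exist.
    """
    if K_now <= 0:
        raise InvalidParameterError(f"K_now must be strictly positive, got {K_now!r}")
    gamma, lambda0, V = params.gamma, params.lambda0, params.V
    if k_now is None:
        k_now = params.k
    rhs = K_now * (delta_l - delta2) + lambda0 - k_now * delta2

    def g(x):
        return gamma * x + lambda0 * math.exp(-(x * x) / (V * V)) - rhs

    # bracket wide enough for both the viscosity- and motor-dominated regimes
    bracket = 10.0 * V * (1.0 + abs(rhs) / lambda0) + (abs(rhs) + 2.0 * lambda0) / gamma
    lo, hi = -bracket, bracket
    if not (g(lo) < 0.0 < g(hi)):
        raise NumericalError(
            f"no sign change on [{lo:.6g}, {hi:.6g}]: g(lo)={g(lo):.6g}, "
            f"g(hi)={g(hi):.6g}, RHS={rhs:.6g}"
        )

    if _monotone_rate_equation(params):
        root = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
    else:
        roots = _scan_roots(g, lo, hi, V)
        if not roots:
            raise NumericalError(
                f"no real root found in [{lo:.6g}, {hi:.6g}] despite bracket sign change"
            )
        if len(roots) > 1:
            warnings.warn(
                f"rate equation has {len(roots)} roots; taking the one nearest "
                f"the previous rate {prev_rate:.6g}",
                MultiRootWarning,
                stacklevel=2,
            )
        root = min(roots, key=lambda r: abs(r - prev_rate))

    # Newton polish: bisection alone leaves residual ~ gamma * xtol
    for _ in range(3):
        gr = g(root)
        if abs(gr) <= 1e-12 * lambda0:
            break
        dg = gamma - 2.0 * lambda0 * root / (V * V) * math.exp(-(root * root) / (V * V))
        if dg == 0:
            break
        root -= gr / dg

    if abs(g(root)) > 1e-10 * lambda0:
        raise NumericalError(
            f"rate residual {g(root):.3e} exceeds tolerance {1e-10 * lambda0:.3e}"
        )
    return root


def _scan_roots(g, lo, hi, V):
    """All roots of ``g`` on [lo, hi] by sign-change scan at resolution ~V/200."""
    n = max(2001, int((hi - lo) / (V / 200.0)) + 1)
    n = min(n, 400001)
    xs = np.linspace(lo, hi, n)
    ys = np.array([g(x) for x in xs])
    roots = []
    sign_change = np.nonzero(np.diff(np.sign(ys)) != 0)[0]
    for i in sign_change:
        roots.append(brentq(g, xs[i], xs[i + 1], xtol=1e-14, rtol=8.9e-16))
    exact = np.nonzero(ys == 0.0)[0]
    roots.extend(xs[i] for i in exact)
    return sorted(set(roots))


def elastic_constant_t(epsilon, t, params):
    """Time-dependent main spring ``K(eps, t)`` (nN/um).

    Compression leaves the main spring untouched; extension softens it as
    fresh actin is recruited, steady state ``K_inf = (1 - alpha*eps) * K0``.
    """
    if np.any(np.asarray(t) < 0):
        raise InvalidParameterError("t must be >= 0")
    if epsilon <= 0:
        return params.K0 if np.isscalar(t) else np.full(np.shape(t), params.K0)
    reduction = params.alpha * epsilon
    if reduction >= 1.0:
        raise ModelValidityError(
            f"alpha*epsilon = {reduction:.3g} >= 1 drives K non-positive"
        )
    t = np.asarray(t, dtype=float)
    K = params.K0 * (1.0 - reduction * (1.0 - np.exp(-t / params.t_star)))
    return float(K) if K.ndim == 0 else K


def secondary_constant(epsilon, params):
    """Strain-gated secondary spring: 0 in compression, ``k`` in extension."""
    return 0.0 if epsilon < 0 else params.k


def radius_short_time(epsilon, params, L0, R0):
    """Elastic radius immediately after the step: ``(K0*L0/sigma)*eps + R0``."""
    if L0 <= 0 or R0 <= 0:
        raise InvalidParameterError("L0 and R0 must be strictly positive")
    return (params.K0 * L0 / params.sigma) * epsilon + R0


def radius_long_time(epsilon, params, L0, R0):
    """Steady-state radius, first order in ``alpha*eps``.

    Compression relaxes fully back to ``R0`` (Maxwell branch).  Extension
    keeps a viscoelastic offset reduced by recruitment softening:
    ``R0 + [k*K0/(k+K0)] * (L0/sigma) * (1 - alpha*k/(k+K0)*eps) * eps``.
    """
    if L0 <= 0 or R0 <= 0:
        raise InvalidParameterError("L0 and R0 must be strictly positive")
    if params.k + params.K0 == 0:
        raise InvalidParameterError("k + K0 must be non-zero")
    if epsilon < 0:
        return R0
    series = params.k * params.K0 / (params.k + params.K0)
    softening = 1.0 - params.alpha * params.k / (params.k + params.K0) * epsilon
    return R0 + series * (L0 / params.sigma) * softening * epsilon


def radius_long_time_exact(epsilon, params, L0, R0):
    """Steady-state radius using the exact softened spring ``K_inf``.

    Same limit as :func:`radius_long_time` but without the first-order
    expansion: ``R0 + [k*K_inf/(k+K_inf)] * (L0/sigma) * eps`` with
    ``K_inf = K0*(1 - alpha*eps)``.
    """
    if epsilon < 0:
        return R0
    K_inf = elastic_constant_t(epsilon, np.inf, params) if epsilon > 0 else params.K0
    if params.k + K_inf == 0:
        raise InvalidParameterError("k + K_inf must be non-zero")
    series = params.k * K_inf / (params.k + K_inf)
    return R0 + series * (L0 / params.sigma) * epsilon


def intensity_model(epsilon, t, alpha, t_star):
    """Relative bundle intensity gain ``alpha*eps*(1 - exp(-t/t_star))``.

    Valid for extension only; for ``eps <= 0`` the recruitment response is
    zero (the compression intensity stays at its prestretch plateau) and a
    :class:`DomainWarning` is emitted.
    """
    if t_star <= 0:
        raise InvalidParameterError("t_star must be strictly positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    if epsilon <= 0:
        warnings.warn(
            "intensity recruitment model is defined for extension only; "
            "returning 0 for eps <= 0",
            DomainWarning,
            stacklevel=2,
        )
        out = np.zeros_like(t)
        return float(out) if out.ndim == 0 else out
    out = alpha * epsilon * (1.0 - np.exp(-t / t_star))
    return float(out) if out.ndim == 0 else out


def density_variation(I_ratio, eps_len):
    """Relative linear-density change ``rho_inf/rho_0 - 1 = I_ratio/(1+eps) - 1``.

    ``rho = total intensity / bundle length``; ``I_ratio`` is the
    steady-to-initial total intensity ratio and ``eps_len`` the length
    strain of the bundle.
    """
    if I_ratio <= 0:
        raise InvalidParameterError("I_ratio must be strictly positive")
    if 1.0 + eps_len <= 0:
        raise InvalidParameterError("1 + eps_len must be strictly positive")
    return I_ratio / (1.0 + eps_len) - 1.0


def elastic_reference(epsilon):
    """Linearized density change of a purely elastic bundle, ``-eps``."""
    return -np.asarray(epsilon, dtype=float) if not np.isscalar(epsilon) else -epsilon


# ---------------------------------------------------------------------------
# forward integration

_REL_TOL = 1e-6  # step-halving convergence criterion on delta2
_MAX_SUBDIV = 64


class _RateSolver:
    """Implicit-rate derivative with continuation of the previous root."""

    def __init__(self, params):
        self.params = params
        self.prev_rate = 0.0

    def __call__(self, t, delta2, dl_fun, K_fun, k_fun):
        rate = solve_rate_implicit(
            delta2,
            float(dl_fun(t)),
            self.params,
            K_fun(t),
            prev_rate=self.prev_rate,
            k_now=k_fun(t),
        )
        self.prev_rate = rate
        return rate


def _rk4_path(delta2_0, nodes, n_sub, params, dl_fun, K_fun, k_fun):
    """Classic RK4 over ``nodes`` with ``n_sub`` substeps per interval."""
    solver = _RateSolver(params)
    out = np.empty(len(nodes))
    out[0] = y = delta2_0
    for i in range(len(nodes) - 1):
        t0, t1 = nodes[i], nodes[i + 1]
        h = (t1 - t0) / n_sub
        for j in range(n_sub):
            t = t0 + j * h
            k1 = solver(t, y, dl_fun, K_fun, k_fun)
            k2 = solver(t + 0.5 * h, y + 0.5 * h * k1, dl_fun, K_fun, k_fun)
            k3 = solver(t + 0.5 * h, y + 0.5 * h * k2, dl_fun, K_fun, k_fun)
            k4 = solver(t + h, y + h * k3, dl_fun, K_fun, k_fun)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not np.isfinite(y):
                raise IntegrationError(
                    f"non-finite state at t = {t + h:.6g}", last_valid_time=t
                )
        out[i + 1] = y
    return out


def _integrate_refined(delta2_0, nodes, params, dl_fun, K_fun, k_fun):
    """Integrate with substep doubling until the trajectory is converged."""
    nodes = np.asarray(nodes, dtype=float)
    prev = _rk4_path(delta2_0, nodes, 1, params, dl_fun, K_fun, k_fun)
    n_sub = 2
    while n_sub <= _MAX_SUBDIV:
        cur = _rk4_path(delta2_0, nodes, n_sub, params, dl_fun, K_fun, k_fun)
        scale = max(np.max(np.abs(cur)), 1e-9)
        if np.max(np.abs(cur - prev)) / scale < _REL_TOL:
            return cur
        prev = cur
        n_sub *= 2
    warnings.warn(
        f"step refinement did not reach {_REL_TOL} relative at {_MAX_SUBDIV} "
        "substeps; returning finest trajectory",
        DomainWarning,
        stacklevel=2,
    )
    return prev


def _simulate_prestretch(protocol, params, strain_gate):
    """Integrate the prestretch ramp + hold; return delta2 at its end."""
    eps_p = protocol.prestretch_epsilon
    dl_end = eps_p * protocol.L0
    tr = dl_end / protocol.rate
    hold = protocol.prestretch_hold

    def dl_fun(t):
        return dl_end * min(max(t / tr, 0.0), 1.0) if tr > 0 else dl_end

    if strain_gate:
        def K_fun(t):
            return elastic_constant_t(eps_p, max(t - tr, 0.0), params)
        def k_fun(t):
            return secondary_constant(eps_p, params)
    else:
        def K_fun(t):
            return params.K0
        def k_fun(t):
            return params.k

    # nodes: a dense ramp, then the hold resolved on the passive time scale
    n_hold = 200
    nodes = np.concatenate(
        [np.linspace(0.0, tr, 8, endpoint=False) if tr > 0 else [0.0],
         np.linspace(tr, tr + hold, n_hold + 1)]
    )
    path = _integrate_refined(0.0, nodes, params, dl_fun, K_fun, k_fun)
    return path[-1]


def simulate_global(protocol, params, t_grid, strain_gate=True):
    """Integrate the bundle equations over a stretch protocol.

    Time zero is the start of the main strain ramp; any prestretch phase is
    integrated internally beforehand to set the initial state.  Returns a
    :class:`BundleTrace` sampled on ``t_grid``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise InvalidParameterError("t_grid must be strictly increasing, length >= 2")
    if t_grid[0] < 0:
        raise InvalidParameterError("t_grid must start at or after the main ramp (t >= 0)")

    eps = protocol.epsilon
    tr = protocol.ramp_duration

    delta2_0 = 0.0
    if protocol.prestretch_epsilon > 0:
        delta2_0 = _simulate_prestretch(protocol, params, strain_gate)

    def dl_fun(t):
        return float(protocol.delta_l(t))

    if strain_gate:
        def K_fun(t):
            return elastic_constant_t(eps, max(t - tr, 0.0), params)
        def k_fun(t):
            return secondary_constant(eps, params)
    else:
        def K_fun(t):
            return params.K0
        def k_fun(t):
            return params.k

    # make sure the ramp end is a node even if absent from the output grid
    nodes = np.union1d(t_grid, [0.0, tr]) if tr > 0 else np.union1d(t_grid, [0.0])
    nodes = nodes[(nodes >= min(0.0, t_grid[0])) & (nodes <= t_grid[-1])]
    path = _integrate_refined(delta2_0, nodes, params, dl_fun, K_fun, k_fun)
    idx = np.searchsorted(nodes, t_grid)
    delta2 = path[idx]

    delta_l = protocol.delta_l(t_grid)
    delta1 = delta_l - delta2
    K_t = np.array([K_fun(t) for t in t_grid])
    lam = K_t * delta1 + params.lambda0
    R = lam / params.sigma
    return BundleTrace(
        t=t_grid, delta1=delta1, delta2=delta2, delta_l=np.asarray(delta_l),
        lam=lam, R=R, K_t=K_t, params=params, protocol=protocol,
    )
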