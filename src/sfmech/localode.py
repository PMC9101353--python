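"""Local dynamics of the relative cortical tension along the bundle.

On a short segment of the fiber the Bischofs balance holds locally,
``sigma_l = lambda_l / r_l``, and the same three-element device governs the
segment strain.  Writing ``xi = (sigma_l - sigma_0)/sigma_0`` for the
relative cortical tension change (proportional to the normalized relative
fluorescence signal) and changing variable to ``chi = tau * xi`` (``chi``
carries units of time, so ``chi_dot`` is dimensionless), the dynamics close
into a single implicit first-order ODE

    chi_dot = f/Gamma - nu*chi - (1/(2*Gamma)) * (1 - exp(-chi_dot**2))

with dimensionless/time groups

    nu    = 2*K0/gamma          passive relaxation rate (1/s)
    tau   = sigma0*R0/(K0*V)    active motor time scale (s)
    f     = K0*eps_l/(2*sigma0) elasticity-to-cortex-tension ratio
    Gamma = gamma*V/(2*sigma0*R0)  contracting vs sliding motor competition

(the four groups satisfy ``Gamma*nu*tau = 1`` when computed from a single
physical parameter set).  Differentiating once gives the equivalent
second-order form

    chi_ddot * (Gamma + chi_dot*exp(-chi_dot**2))
        = -nu*f + nu**2*Gamma*chi + (nu/2)*(1 - exp(-chi_dot**2))

which accepts independent initial conditions ``(chi0, chi_dot0)`` — the
form used when fitting measured intensity traces, with the initial
conditions taken from the data's smoothed derivatives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import (
    DomainWarning,
    InvalidParameterError,
    MultiRootWarning,
    NumericalError,
)

__all__ = [
    "LocalOdeParams",
    "ChiTrace",
    "chi_steady_state",
    "solve_chidot",
    "simulate_local_chi",
]

#: ratio k/K0 beyond which the reduced (k/K0 = 1) form is flagged
_K_RATIO_FLAG = 0.25


@dataclass(frozen=True)
class LocalOdeParams:
    """Dimensionless groups of the local ODE plus their physical anchors."""

    nu: float
    tau: float
    f: float
    Gamma: float
    sigma0: float = 0.035
    lambda0_local: float = 2.3
    R0: float = 65.6

    def __post_init__(self):
        for name in ("nu", "tau", "Gamma", "sigma0", "R0"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise InvalidParameterError(
                    f"{name} must be strictly positive, got {value!r}"
                )
        if self.f < 0:
            raise InvalidParameterError(f"f must be >= 0, got {self.f!r}")

    @classmethod
    def from_global(cls, params, eps_l, R0=None, sigma0=None, k_ratio=None):
        """Derive the groups from one physical parameter set.

        ``sigma0`` defaults to the global cortical tension; the identity
        ``Gamma*nu*tau = 1`` then holds by construction.  A ``k_ratio``
        (= k/K0) far from 1 is flagged: the reduced ODE assumes k ~ K0.
        """
        sigma0 = params.sigma if sigma0 is None else sigma0
        R0 = params.lambda0 / params.sigma if R0 is None else R0
        if k_ratio is None and params.K0 > 0:
            k_ratio = params.k / params.K0
        if k_ratio is not None and abs(k_ratio - 1.0) > _K_RATIO_FLAG:
            warnings.warn(
                f"k/K0 = {k_ratio:.3g} deviates from 1 by more than "
                f"{_K_RATIO_FLAG:.0%}; the reduced local ODE assumes k ~ K0",
                DomainWarning,
                stacklevel=2,
            )
        return cls(
            nu=2.0 * params.K0 / params.gamma,
            tau=sigma0 * R0 / (params.K0 * params.V),
            f=params.K0 * eps_l / (2.0 * sigma0),
            Gamma=params.gamma * params.V / (2.0 * sigma0 * R0),
            sigma0=sigma0,
            lambda0_local=sigma0 * R0,
            R0=R0,
        )

    @property
    def identity_gamma_nu_tau(self):
        """Diagnostic ``Gamma*nu*tau`` (1 for a consistent physical set)."""
        return self.Gamma * self.nu * self.tau


@dataclass
class ChiTrace:
    """Trajectory of the local tension variable."""

    t: np.ndarray
    chi: np.ndarray
    chidot: np.ndarray
    xi: np.ndarray  # chi / tau, the relative cortical tension change
    params: LocalOdeParams | None = None


def chi_steady_state(p: LocalOdeParams) -> float:
    """Closed-form fixed point ``chi_ss = f / (nu * Gamma)`` (s)."""
    return p.f / (p.nu * p.Gamma)


def _rhs_first_order(p, chi):
    """Right-hand side of the first-order form before the implicit term."""
    return p.f / p.Gamma - p.nu * chi


def solve_chidot(p, chi, prev=0.0):
    """Solve ``x = f/Gamma - nu*chi - (1/(2*Gamma))*(1 - exp(-x**2))`` for x.

    Monotone whenever ``Gamma >= exp(-1/2)/sqrt(2) ~ 0.429``; below that the
    root nearest ``prev`` is used (continuation) and a warning is emitted if
    several roots exist.
    """
    a = _rhs_first_order(p, chi)
    b = 1.0 / (2.0 * p.Gamma)

    def h(x):
        return x - a + b * (1.0 - math.exp(-x * x))

    lo, hi = min(a, 0.0) - 2.0 * b - 1.0, max(a, 0.0) + 1.0
    if not (h(lo) < 0.0 < h(hi)):
        raise NumericalError(
            f"no bracket for chi_dot: h({lo:.4g})={h(lo):.4g}, h({hi:.4g})={h(hi):.4g}"
        )
    if p.Gamma >= math.exp(-0.5) / math.sqrt(2.0):
        return brentq(h, lo, hi, xtol=1e-14, rtol=8.9e-16)
    xs = np.linspace(lo, hi, 4001)
    ys = np.array([h(x) for x in xs])
    idx = np.nonzero(np.diff(np.sign(ys)) != 0)[0]
    roots = [brentq(h, xs[i], xs[i + 1], xtol=1e-14, rtol=8.9e-16) for i in idx]
    if not roots:
        raise NumericalError("sign-change scan found no chi_dot root")
    if len(roots) > 1:
        warnings.warn(
            f"chi_dot equation has {len(roots)} roots; continuation from {prev:.4g}",
            MultiRootWarning,
            stacklevel=2,
        )
    return min(roots, key=lambda r: abs(r - prev))


def _integrate_first_order(p, chi0, t_grid):
    def refine(n_sub):
        ys = np.empty(len(t_grid))
        ds = np.empty(len(t_grid))
        y = chi0
        prev_local = solve_chidot(p, y)
        ys[0], ds[0] = y, prev_local
        for i in range(len(t_grid) - 1):
            h = (t_grid[i + 1] - t_grid[i]) / n_sub
            for _ in range(n_sub):
                k1 = solve_chidot(p, y, prev_local)
                k2 = solve_chidot(p, y + 0.5 * h * k1, k1)
                k3 = solve_chidot(p, y + 0.5 * h * k2, k2)
                k4 = solve_chidot(p, y + h * k3, k3)
                y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                prev_local = k4
            ys[i + 1] = y
            ds[i + 1] = solve_chidot(p, y, prev_local)
        return ys, ds

    prev_ys, prev_ds = refine(1)
    n_sub = 2
    while n_sub <= 32:
        ys, ds = refine(n_sub)
        scale = max(np.max(np.abs(ys)), 1e-12)
        if np.max(np.abs(ys - prev_ys)) / scale < 1e-9:
            return ys, ds
        prev_ys, prev_ds = ys, ds
        n_sub *= 2
    return prev_ys, prev_ds


class _EvalBudgetExceeded(Exception):
    pass


def _integrate_second_order(p, chi0, chidot0, t_grid, rtol=1e-10, atol=1e-12,
                            cap_step=True, max_rhs_evals=200000):
    nu, f, Gamma = p.nu, p.f, p.Gamma
    singular = {"hit": False}
    n_evals = [0]

    def rhs(t, y):
        n_evals[0] += 1
        if n_evals[0] > max_rhs_evals:
            raise _EvalBudgetExceeded
        chi, chidot = y
        e = math.exp(-chidot * chidot)
        denom = Gamma + chidot * e
        if abs(denom) < 1e-8:
            singular["hit"] = True
            denom = math.copysign(1e-8, denom if denom != 0 else 1.0)
        num = -nu * f + nu * nu * Gamma * chi + 0.5 * nu * (1.0 - e)
        return [chidot, num / denom]

    # differentiation introduces a spurious growing mode (~exp(+nu*t));
    # cap the state so off-manifold parameter guesses fail fast, not slowly
    chi_cap = 1e3 * (1.0 + abs(chi0) + abs(f / (nu * Gamma)))

    def escape(t, y):
        return min(chi_cap - abs(y[0]), 50.0 - abs(y[1]))

    escape.terminal = True

    try:
        sol = solve_ivp(
            rhs, (t_grid[0], t_grid[-1]), [chi0, chidot0], t_eval=t_grid,
            method="RK45", rtol=rtol, atol=atol, events=escape,
            max_step=(t_grid[-1] - t_grid[0]) / 50 if cap_step else np.inf,
        )
    except _EvalBudgetExceeded:
        raise NumericalError(
            f"chi integration exceeded {max_rhs_evals} derivative evaluations "
            "(stiff/singular parameter region)"
        ) from None
    if not sol.success:
        raise NumericalError(f"second-order chi integration failed: {sol.message}")
    if len(sol.t) < len(t_grid):
        raise NumericalError(
            f"chi trajectory escaped (|chi| > {chi_cap:.3g} or |chi_dot| > 50) "
            f"at t = {sol.t[-1] if len(sol.t) else t_grid[0]:.4g} s"
        )
    return sol.y[0], sol.y[1], singular["hit"]


def simulate_local_chi(p, chi0=None, chidot0=None, t_grid=None, form="first",
                       rtol=1e-10, atol=1e-12, cap_step=True,
                       max_rhs_evals=200000):
    """Integrate the local tension ODE; returns a :class:`ChiTrace`.

    Defaults: ``chi0 = 2*f*tau`` (instantaneous elastic response of the
    segment, ``xi(0) = K0*eps_l/sigma0 = 2f`` with ``k = K0``) and
    ``chidot0`` solving the first-order form at ``chi0``.  ``form`` selects
    the first-order implicit integration (continuation root solve) or the
    second-order form with free ``(chi0, chidot0)``; with consistent initial
    conditions the two agree to integration tolerance.  If the second-order
    form hits its singular denominator the first-order form takes over.
    """
    if t_grid is None:
        raise InvalidParameterError("t_grid is required")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise InvalidParameterError("t_grid must be strictly increasing, length >= 2")
    if chi0 is None:
        chi0 = 2.0 * p.f * p.tau
    if form == "first":
        chi, chidot = _integrate_first_order(p, chi0, t_grid)
    elif form == "second":
        if chidot0 is None:
            chidot0 = solve_chidot(p, chi0)
        chi, chidot, singular = _integrate_second_order(
            p, chi0, chidot0, t_grid, rtol=rtol, atol=atol, cap_step=cap_step,
            max_rhs_evals=max_rhs_evals)
        if singular:
            warnings.warn(
                "second-order form crossed its singular denominator; "
                "switching to the first-order form",
                DomainWarning,
                stacklevel=2,
            )
            chi, chidot = _integrate_first_order(p, chi0, t_grid)
    else:
        raise InvalidParameterError(f"form must be 'first' or 'second', got {form!r}")
    return ChiTrace(t=t_grid, chi=chi, chidot=chidot, xi=chi / p.tau, params=p)
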