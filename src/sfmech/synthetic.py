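"""Synthetic microscopy observables with exact ground truth.

Every input the analysis consumes can be generated here: radius-of-curvature
time series, raw intensity kymographs (end peaks, mid-fiber valley,
recruitment dynamics, photobleaching), rendered arc image stacks with edge
coordinates, and local tension traces.  Defaults reproduce the study
conditions: bundles of chord 36.47 um and radius 65.60 um, steps up to 40%
strain at 100 um/s, a 60-min prestretch before compression, images every
2 s for 900 s, recruitment index 0.64 with a 427 s time scale, and
relaxation near 300 s.  Each generator's output carries the ground truth
needed to score any downstream estimate, and a seed fully determines the
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidParameterError
from .kymograph import Kymograph
from .localode import LocalOdeParams, simulate_local_chi
from .model import (
    GlobalMechParams,
    StretchProtocol,
    intensity_model,
    simulate_global,
)

__all__ = [
    "GeometryConfig",
    "NoiseConfig",
    "SamplingConfig",
    "GeneratorConfig",
    "default_params",
    "default_protocol",
    "default_config",
    "sample_replicates",
    "generate_radius_trace",
    "generate_kymograph",
    "generate_arc_stack",
    "generate_intensity_traces",
    "generate_local_traces",
]

# study-condition constants
_SHORT_SLOPE = 189.5   # um, elastic radius-vs-strain slope (= E*A/sigma)
_LONG_SLOPE = 104.9    # um, steady-state extension slope
_E = 11.3              # nN/um^2
_RELAX_T = 300.0       # s, passive relaxation time scale gamma/(2*K0)


@dataclass(frozen=True)
class GeometryConfig:
    L0: float = 36.47
    R0: float = 65.60
    A: float = 0.6
    L0_sd: float = 4.21
    R0_sd: float = 5.44
    A_sd: float = 0.2


@dataclass(frozen=True)
class NoiseConfig:
    edge_point_sd: float = 0.3      # um, additive on edge coordinates
    radius_sd: float = 1.5          # um, propagated point noise on R
    intensity_cv: float = 0.05      # multiplicative CV on intensity
    tau_b: float = 1500.0           # s, photobleaching decay


@dataclass(frozen=True)
class SamplingConfig:
    dt: float = 2.0
    duration: float = 900.0
    pixel_size: float = 0.2


@dataclass(frozen=True)
class GeneratorConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    params: GlobalMechParams = None
    protocol: StretchProtocol = None
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    seed: int = 0
    n_replicates: int = 12

    def __post_init__(self):
        if self.params is None:
            object.__setattr__(self, "params", default_params(self.geometry))
        if self.protocol is None:
            object.__setattr__(self, "protocol", default_protocol(0.2, self.geometry))

    def rng(self):
        return np.random.default_rng(self.seed)

    def t_grid(self):
        n = int(round(self.sampling.duration / self.sampling.dt))
        return self.sampling.dt * np.arange(n + 1)


def default_params(geometry: GeometryConfig | None = None) -> GlobalMechParams:
    """Bundle constants consistent with the measured slopes and geometry.

    ``K0 = E*A/L0``, ``sigma = E*A/189.5``, ``K0/k`` from the slope ratio,
    ``gamma = 2*K0*300 s``, ``lambda0 = sigma*R0``, motor scale 0.1 um/s,
    recruitment ``alpha = 0.64`` with ``t* = 427 s``.
    """
    g = geometry or GeometryConfig()
    EA = _E * g.A
    K0 = EA / g.L0
    sigma = EA / _SHORT_SLOPE
    K0_over_k = _SHORT_SLOPE / _LONG_SLOPE - 1.0
    return GlobalMechParams(
        K0=K0,
        k=K0 / K0_over_k,
        gamma=2.0 * K0 * _RELAX_T,
        lambda0=sigma * g.R0,
        V=0.1,
        sigma=sigma,
        E=_E,
        A=g.A,
        alpha=0.64,
        t_star=427.0,
    )


def default_protocol(epsilon, geometry: GeometryConfig | None = None) -> StretchProtocol:
    """Step protocol at the study rate; compression is applied after a
    60-min prestretch of the same magnitude."""
    g = geometry or GeometryConfig()
    if epsilon >= 0:
        return StretchProtocol(epsilon=epsilon, rate=100.0, L0=g.L0)
    return StretchProtocol(
        epsilon=epsilon, rate=100.0, L0=g.L0,
        prestretch_epsilon=abs(epsilon), prestretch_hold=3600.0,
        direction="compression",
    )


def default_config(epsilon=0.2, seed=0, **overrides) -> GeneratorConfig:
    geometry = overrides.pop("geometry", GeometryConfig())
    return GeneratorConfig(
        geometry=geometry,
        params=overrides.pop("params", default_params(geometry)),
        protocol=overrides.pop("protocol", default_protocol(epsilon, geometry)),
        seed=seed,
        **overrides,
    )


def sample_replicates(cfg: GeneratorConfig, rng=None):
    """Per-replicate configs with population variability in (L0, R0, A).

    Gaussian draws truncated at +-3 SD; the mechanical constants are
    re-derived from each replicate's geometry so every replicate is an
    internally consistent bundle.
    """
    rng = cfg.rng() if rng is None else rng

    def draw(mean, sd):
        while True:
            v = rng.normal(mean, sd)
            if abs(v - mean) <= 3.0 * sd and v > 0:
                return v

    out = []
    g0 = cfg.geometry
    for _ in range(cfg.n_replicates):
        g = GeometryConfig(
            L0=draw(g0.L0, g0.L0_sd), R0=draw(g0.R0, g0.R0_sd),
            A=draw(g0.A, g0.A_sd),
            L0_sd=g0.L0_sd, R0_sd=g0.R0_sd, A_sd=g0.A_sd,
        )
        protocol = replace(cfg.protocol, L0=g.L0)
        out.append(replace(cfg, geometry=g, params=default_params(g),
                           protocol=protocol))
    return out


@dataclass
class RadiusTraceSample:
    t: np.ndarray
    R: np.ndarray          # noisy observable
    R_true: np.ndarray     # noiseless ground truth
    truth: dict


def generate_radius_trace(cfg: GeneratorConfig, rng=None) -> RadiusTraceSample:
    """Simulated radius time course with measurement noise."""
    rng = cfg.rng() if rng is None else rng
    t = cfg.t_grid()
    trace = simulate_global(cfg.protocol, cfg.params, t, strain_gate=True)
    noise = rng.normal(0.0, cfg.noise.radius_sd, size=len(t))
    return RadiusTraceSample(
        t=t,
        R=trace.R + noise,
        R_true=trace.R.copy(),
        truth={
            "params": cfg.params,
            "protocol": cfg.protocol,
            "geometry": cfg.geometry,
            "R0": cfg.params.R0,
            "radius_sd": cfg.noise.radius_sd,
        },
    )


@dataclass
class KymographSample:
    kym: Kymograph
    truth: dict


def generate_kymograph(
    cfg: GeneratorConfig,
    spatial_template="bimodal",
    custom_profile=None,
    tau_fa=178.5,
    tau_fa_fast=40.0,
    tau_msf=387.9,
    fa_amp_per_strain=1.2,
    msf_amp_per_strain=1.0,
    peak_contrast=0.8,
    valley_contrast=0.3,
    bleach=True,
    noisy=True,
    quiet_prefix=0.0,
    rng=None,
) -> KymographSample:
    """Raw intensity kymograph of one bundle under the configured protocol.

    Spatial profile: two focal-adhesion end peaks and a mid-fiber valley
    (``bimodal``), flat, or ``custom``.  Temporal structure: the FA regions
    overshoot as a difference of exponentials with slow scale ``tau_fa``;
    the mid-fiber grows with scale ``tau_msf``; the remaining bundle carries
    the residual that pins the bundle-total trace to the recruitment law
    ``alpha*eps*(1-exp(-t/t*))``.  ``quiet_prefix`` seconds of pre-stimulus
    acquisition (dynamics frozen, bleaching active) are prepended at
    negative times — the window the bleach correction is meant to be fitted
    on.  Bleach decay and multiplicative noise are applied last.
    """
    rng = cfg.rng() if rng is None else rng
    ds = cfg.sampling.pixel_size
    L = cfg.geometry.L0
    s = np.arange(0.0, L + ds / 2.0, ds)
    t = cfg.t_grid()
    if quiet_prefix > 0:
        n_pre = int(round(quiet_prefix / cfg.sampling.dt))
        t = np.concatenate([-cfg.sampling.dt * np.arange(n_pre, 0, -1), t])
    t_dyn = np.clip(t, 0.0, None)  # dynamics frozen before the stimulus
    eps = cfg.protocol.epsilon

    s_fa_left, s_fa_right = 1.5, L - 1.5
    s_msf = L / 2.0
    w_fa, w_msf = 2.5, 6.0

    def gauss(x, mu, w):
        return np.exp(-((x - mu) ** 2) / (2.0 * w * w))

    if spatial_template == "bimodal":
        P = (1.0 + peak_contrast * (gauss(s, s_fa_left, w_fa) + gauss(s, s_fa_right, w_fa))
             - valley_contrast * gauss(s, s_msf, w_msf))
    elif spatial_template == "flat":
        P = np.ones_like(s)
    elif spatial_template == "custom":
        if custom_profile is None:
            raise InvalidParameterError("custom template requires custom_profile")
        P = np.asarray(custom_profile, dtype=float)
        if P.shape != s.shape:
            raise InvalidParameterError(
                f"custom_profile length {len(P)} != arc grid length {len(s)}")
    else:
        raise InvalidParameterError(f"unknown spatial_template {spatial_template!r}")

    if eps > 0:
        g_total = intensity_model(eps, t_dyn, cfg.params.alpha, cfg.params.t_star)
        u_fa = fa_amp_per_strain * eps * (
            np.exp(-t_dyn / tau_fa) - np.exp(-t_dyn / tau_fa_fast))
        u_msf = msf_amp_per_strain * eps * (1.0 - np.exp(-t_dyn / tau_msf))
    else:
        # compression: intensity plateaus set by the prestretch, no new dynamics
        g_total = np.zeros_like(t)
        u_fa = np.zeros_like(t)
        u_msf = np.zeros_like(t)

    w_left = gauss(s, s_fa_left, w_fa)
    w_right = gauss(s, s_fa_right, w_fa)
    w_mid = gauss(s, s_msf, w_msf)
    D = (w_left + w_right)[:, None] * u_fa[None, :] + w_mid[:, None] * u_msf[None, :]
    # residual carried by the bundle outside the landmark regions, pinning
    # the total trace to the recruitment law without touching FA/mSF shapes
    w_bg = np.clip(1.0 - (w_left + w_right + w_mid), 0.0, None)
    meanP = P.mean()
    bg_weight = float((P * w_bg).mean())
    c = (g_total * meanP - (P[:, None] * D).mean(axis=0)) / bg_weight
    I = P[:, None] * (1.0 + D + w_bg[:, None] * c[None, :])

    tau_b = cfg.noise.tau_b if bleach else np.inf
    if np.isfinite(tau_b):
        I = I * np.exp(-(t - t[0]) / tau_b)[None, :]
    if noisy and cfg.noise.intensity_cv > 0:
        I = I * (1.0 + cfg.noise.intensity_cv * rng.standard_normal(I.shape))
    I = np.clip(I, 0.0, None)

    kym = Kymograph(s=s, t=t, I=I, state="raw",
                    pixel_size=ds, dt=cfg.sampling.dt)
    truth = {
        "profile": P,
        "positions": {"fa_left": s_fa_left, "msf": s_msf, "fa_right": s_fa_right},
        "tau_fa": tau_fa, "tau_fa_fast": tau_fa_fast, "tau_msf": tau_msf,
        "alpha": cfg.params.alpha, "t_star": cfg.params.t_star,
        "tau_b": tau_b, "epsilon": eps,
        "total_relative": g_total,
        "fa_trace": u_fa, "msf_trace": u_msf,
    }
    return KymographSample(kym=kym, truth=truth)


@dataclass
class ArcStackSample:
    stack: np.ndarray        # (n_frames, ny, nx) counts
    t: np.ndarray
    edges: list              # per-frame (n_pts, 2) ground-truth edge points, um
    R_true: np.ndarray
    truth: dict


def generate_arc_stack(
    cfg: GeneratorConfig,
    pixel_size=0.5,
    canvas=None,
    amplitude=800.0,
    arc_width=0.8,
    background=20.0,
    read_noise=2.0,
    n_edge_points=50,
    noisy=True,
    rng=None,
) -> ArcStackSample:
    """Rendered fluorescent-arc image stack following the simulated R(t).

    Anti-aliased Gaussian-profile arc between two fixed anchor points with
    Poisson-Gaussian camera noise; ground-truth edge coordinates (um,
    origin lower-left) are emitted per frame, with the configured edge
    point noise added so they double as realistic edge inputs.
    """
    rng = cfg.rng() if rng is None else rng
    t = cfg.t_grid()
    trace = simulate_global(cfg.protocol, cfg.params, t, strain_gate=True)
    R_true = trace.R
    L = cfg.geometry.L0

    h_all = R_true - np.sqrt(np.clip(R_true**2 - (L / 2) ** 2, 0.0, None))
    h_max = float(h_all.max())
    if canvas is None:
        nx = int(math.ceil((L + 8.0) / pixel_size))
        ny = int(math.ceil((h_max + 8.0) / pixel_size))
    else:
        ny, nx = canvas
    y_chord = 3.0
    x_mid = nx * pixel_size / 2.0
    if (x_mid - L / 2.0 < 0 or x_mid + L / 2.0 > nx * pixel_size
            or y_chord + h_max + 3.0 * arc_width > ny * pixel_size):
        raise InvalidParameterError("arc exceeds canvas; enlarge canvas")

    xs = (np.arange(nx) + 0.5) * pixel_size
    ys_img = (ny - np.arange(ny) - 0.5) * pixel_size  # row -> um, origin lower-left
    X, Y = np.meshgrid(xs, ys_img)

    stack = np.empty((len(t), ny, nx))
    edges = []
    for i, R in enumerate(R_true):
        if R <= L / 2.0:
            raise InvalidParameterError(f"radius {R:.3g} um below half-chord; degenerate arc")
        h = R - math.sqrt(R * R - (L / 2.0) ** 2)
        cy = y_chord + h - R
        theta_h = math.asin((L / 2.0) / R)
        d = np.abs(np.hypot(X - x_mid, Y - cy) - R)
        ang = np.arctan2(Y - cy, X - x_mid)
        inside = np.abs(ang - math.pi / 2.0) <= theta_h
        img = background + amplitude * np.exp(-d * d / (2.0 * arc_width**2)) * inside
        if noisy:
            img = rng.poisson(img).astype(float) + rng.normal(0.0, read_noise, img.shape)
        stack[i] = img

        ang_pts = math.pi / 2.0 + theta_h * np.linspace(-1.0, 1.0, n_edge_points)
        ex = x_mid + R * np.cos(ang_pts)
        ey = cy + R * np.sin(ang_pts)
        pts = np.column_stack([ex, ey])
        if noisy and cfg.noise.edge_point_sd > 0:
            pts = pts + rng.normal(0.0, cfg.noise.edge_point_sd, pts.shape)
        edges.append(pts)

    return ArcStackSample(
        stack=stack, t=t, edges=edges, R_true=R_true,
        truth={"params": cfg.params, "protocol": cfg.protocol,
               "pixel_size": pixel_size, "y_chord": y_chord,
               "amplitude": amplitude, "arc_width": arc_width},
    )


def generate_intensity_traces(cfg: GeneratorConfig, epsilon, n_traces=10, rng=None):
    """Noisy bundle-total relative intensity traces for one strain level.

    ``Delta I/I0 (t) = alpha*eps*(1-exp(-t/t*))`` with multiplicative
    Gaussian noise of the configured CV applied to the intensity itself
    (``1 + Delta I/I0``).  Returns (t, traces[n, len(t)], truth).
    """
    rng = cfg.rng() if rng is None else rng
    t = cfg.t_grid()
    clean = intensity_model(epsilon, t, cfg.params.alpha, cfg.params.t_star)
    cv = cfg.noise.intensity_cv
    traces = np.empty((n_traces, len(t)))
    for i in range(n_traces):
        noisy = (1.0 + clean) * (1.0 + cv * rng.standard_normal(len(t)))
        traces[i] = noisy - 1.0
    truth = {"alpha": cfg.params.alpha, "t_star": cfg.params.t_star,
             "epsilon": epsilon, "plateau": cfg.params.alpha * epsilon}
    return t, traces, truth


def generate_local_traces(p: LocalOdeParams, n_traces, t_grid, cv=0.05,
                          chi0=None, rng=None, seed=0):
    """Noisy local tension (xi) traces from the first-order chi dynamics.

    The noiseless trajectory starts from ``chi0`` (default the elastic
    response ``2*f*tau``); each trace gets independent multiplicative
    Gaussian noise of coefficient of variation ``cv``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    t_grid = np.asarray(t_grid, dtype=float)
    clean = simulate_local_chi(p, chi0=chi0, t_grid=t_grid, form="first")
    traces = clean.xi[None, :] * (1.0 + cv * rng.standard_normal((n_traces, len(t_grid))))
    truth = {
        "params": p,
        "xi": clean.xi,
        "chi0": clean.chi[0],
        "chidot0": clean.chidot[0],
        "xi_ss": p.f / (p.nu * p.Gamma * p.tau),
    }
    return traces, truth
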