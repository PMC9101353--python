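"""Intensity kymographs along a bundle: extraction, normalization, landmarks.

A kymograph is an arc-length x time grid of fluorescence intensity sampled
along the fiber.  The processing chain is strictly one-way:

    raw -> bleach_corrected -> normalized_relative

Photobleaching is removed by fitting an exponential decay to the total
intensity on a stimulus-free window and dividing it out; the relative
normalization turns the signal into ``(I - I0)/I0`` per position (or per
region), the quantity the recruitment and local tension models speak about.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .exceptions import (
    CorrectionFailureError,
    InvalidParameterError,
    KymographStateError,
    LandmarkAmbiguityWarning,
)

__all__ = [
    "Kymograph",
    "extract_kymograph",
    "photobleach_correct",
    "normalize_relative",
    "segment_average",
    "locate_landmarks",
    "total_trace",
]

_STATES = ("raw", "bleach_corrected", "normalized_relative")


@dataclass
class Kymograph:
    """Arc-length x time intensity grid.

    ``I`` has shape ``(len(s), len(t))``; ``state`` records the
    normalization stage; ``meta`` carries processing results such as the
    fitted bleaching constant ``tau_b``.
    """

    s: np.ndarray
    t: np.ndarray
    I: np.ndarray
    state: str = "raw"
    pixel_size: float = 1.0
    dt: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.I.shape != (len(self.s), len(self.t)):
            raise InvalidParameterError(
                f"I shape {self.I.shape} does not match (len(s), len(t)) = "
                f"({len(self.s)}, {len(self.t)})"
            )
        if np.any(np.diff(self.s) <= 0):
            raise InvalidParameterError("s must be strictly increasing")
        if np.any(np.diff(self.t) <= 0):
            raise InvalidParameterError("t must be strictly increasing")
        if self.state not in _STATES:
            raise InvalidParameterError(f"unknown state {self.state!r}")
        if self.state == "raw" and (not np.all(np.isfinite(self.I)) or np.any(self.I < 0)):
            raise InvalidParameterError("raw kymograph must be finite and >= 0")

    @property
    def length(self):
        return float(self.s[-1] - self.s[0])

    def to_csv(self, path):
        """Matrix CSV (rows: s, columns: t) plus a JSON sidecar."""
        path = Path(path)
        frame = pd.DataFrame(self.I, index=self.s, columns=self.t)
        frame.to_csv(path, index_label="s_um")
        sidecar = {
            "s_um": self.s.tolist(),
            "t_s": self.t.tolist(),
            "state": self.state,
            "pixel_size_um": self.pixel_size,
            "dt_s": self.dt,
            "meta": {k: v for k, v in self.meta.items() if _json_safe(v)},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path):
        path = Path(path)
        frame = pd.read_csv(path, index_col=0)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            s=np.asarray(sidecar["s_um"]),
            t=np.asarray(sidecar["t_s"]),
            I=frame.to_numpy(),
            state=sidecar["state"],
            pixel_size=sidecar["pixel_size_um"],
            dt=sidecar["dt_s"],
            meta=sidecar.get("meta", {}),
        )


def _json_safe(v):
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _window_mask(t, window):
    lo, hi = window
    return (t >= lo) & (t <= hi)


def extract_kymograph(stack, path_um, width, pixel_size, dt, t0=0.0):
    """Sample an image stack along a polyline, averaged transversely.

    ``stack`` is (n_frames, ny, nx); ``path_um`` an (m, 2) polyline in um
    (origin lower-left, pixel centers at half-integers); ``width`` the
    transverse averaging extent in um.  Bilinear sub-pixel sampling; the
    arc-length grid has pixel resolution.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise InvalidParameterError("stack must be (n_frames, ny, nx)")
    if width < 0:
        raise InvalidParameterError("width must be >= 0")
    path_um = np.asarray(path_um, dtype=float)
    n_frames, ny, nx = stack.shape
    bad = [
        i for i, (x, y) in enumerate(path_um)
        if not (0.0 <= x <= nx * pixel_size and 0.0 <= y <= ny * pixel_size)
    ]
    if bad:
        raise InvalidParameterError(
            f"path vertices outside image bounds at indices {bad}: "
            f"{[tuple(path_um[i]) for i in bad]}"
        )

    # resample polyline at pixel resolution
    seg = np.diff(path_um, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arclen[-1]
    n_s = max(int(round(total / pixel_size)) + 1, 2)
    s_grid = np.linspace(0.0, total, n_s)
    xs = np.interp(s_grid, arclen, path_um[:, 0])
    ys = np.interp(s_grid, arclen, path_um[:, 1])

    # unit normals along the resampled path
    dx = np.gradient(xs)
    dy = np.gradient(ys)
    norm = np.hypot(dx, dy)
    norm[norm == 0] = 1.0
    nx_, ny_ = -dy / norm, dx / norm

    if width > 0:
        n_off = max(int(round(width / (pixel_size / 2.0))) + 1, 3)
        offsets = np.linspace(-width / 2.0, width / 2.0, n_off)
    else:
        offsets = np.array([0.0])

    I = np.zeros((n_s, n_frames))
    for off in offsets:
        px = xs + off * nx_
        py = ys + off * ny_
        col = px / pixel_size - 0.5
        row = ny - py / pixel_size - 0.5
        for fi in range(n_frames):
            I[:, fi] += map_coordinates(
                stack[fi], [row, col], order=1, mode="nearest"
            )
    I /= len(offsets)
    t = t0 + dt * np.arange(n_frames)
    return Kymograph(s=s_grid, t=t, I=I, state="raw", pixel_size=pixel_size, dt=dt)


def photobleach_correct(kym, fit_window):
    """Divide out an exponential bleach decay fitted on a quiet window.

    Fits ``I_total(t) = C * exp(-t/tau_b)`` (log-linear least squares) on
    ``fit_window = (t_lo, t_hi)`` of the spatially averaged intensity, then
    divides the whole kymograph by ``exp(-t/tau_b)``.  A flat window yields
    ``tau_b = inf`` (identity); a negative fitted ``tau_b`` (brightening)
    raises :class:`CorrectionFailureError`.
    """
    if kym.state != "raw":
        raise KymographStateError(
            f"photobleach_correct requires state 'raw', got {kym.state!r}"
        )
    mask = _window_mask(kym.t, fit_window)
    if np.count_nonzero(mask) < 10:
        raise InvalidParameterError("fit_window must contain at least 10 samples")
    tw = kym.t[mask]
    total = kym.I[:, mask].mean(axis=0)
    if np.any(total <= 0):
        raise CorrectionFailureError("non-positive total intensity in fit window")
    slope, intercept = np.polyfit(tw, np.log(total), 1)
    if abs(slope) * (kym.t[-1] - kym.t[0]) < 1e-10:
        slope = 0.0  # numerically flat: no bleaching
    if slope > 0:
        raise CorrectionFailureError(
            f"fitted decay rate is negative (tau_b = {-1.0 / slope:.4g} s <= 0): "
            "intensity brightens over the fit window"
        )
    tau_b = np.inf if slope == 0 else -1.0 / slope
    decay = np.exp(slope * kym.t)  # == exp(-t/tau_b)
    out = replace(
        kym,
        I=kym.I / decay[None, :],
        state="bleach_corrected",
        meta={**kym.meta, "tau_b_s": float(tau_b), "bleach_C": float(np.exp(intercept))},
    )
    return out


def normalize_relative(kym, baseline_window, mode="per_position"):
    """Relative intensity change ``(I - I0)/I0`` with a baseline-window mean.

    ``mode='per_position'`` normalizes each arc-length sample by its own
    baseline; ``mode='per_region'`` uses the bundle-average baseline for
    every position.  The bundle-total trace ``Delta I / I0`` is stored in
    ``meta['total_relative']``.
    """
    if kym.state != "bleach_corrected":
        raise KymographStateError(
            f"normalize_relative requires state 'bleach_corrected', got {kym.state!r}"
        )
    mask = _window_mask(kym.t, baseline_window)
    if not np.any(mask):
        raise InvalidParameterError("baseline_window selects no samples")
    base = kym.I[:, mask].mean(axis=1)
    if mode == "per_region":
        base = np.full_like(base, base.mean())
    elif mode != "per_position":
        raise InvalidParameterError(f"unknown mode {mode!r}")
    bad = np.nonzero(base <= 0)[0]
    if len(bad):
        raise InvalidParameterError(
            f"non-positive baseline at s = {kym.s[bad][:10].tolist()} um"
        )
    rel = (kym.I - base[:, None]) / base[:, None]
    total0 = kym.I[:, mask].mean()
    total_rel = (kym.I.mean(axis=0) - total0) / total0
    return replace(
        kym,
        I=rel,
        state="normalized_relative",
        meta={**kym.meta, "total_relative": total_rel, "baseline_mode": mode},
    )


def total_trace(kym):
    """Bundle-total relative intensity trace from a normalized kymograph."""
    if kym.state != "normalized_relative":
        raise KymographStateError("total_trace requires a normalized kymograph")
    return np.asarray(kym.meta["total_relative"])


def segment_average(kym, segment_length):
    """Average into contiguous segments from the adhesion-proximal end.

    Non-overlapping tiles of ``segment_length`` um starting at ``s[0]``; a
    trailing remainder shorter than half a segment is merged into the last
    full segment, otherwise it forms its own (short) segment.  The output
    ``s`` grid holds segment midpoints.
    """
    if segment_length < kym.pixel_size:
        raise InvalidParameterError("segment_length must be >= pixel_size")
    span = kym.s[-1] - kym.s[0] + kym.pixel_size  # sample-supported length
    if segment_length > span:
        raise InvalidParameterError(
            f"segment_length {segment_length} um exceeds bundle length {span:.3g} um"
        )
    n_full = int(span // segment_length)
    remainder = span - n_full * segment_length
    edges = kym.s[0] + segment_length * np.arange(n_full + 1)
    if remainder >= segment_length / 2.0:
        edges = np.append(edges, kym.s[0] + span)
    else:
        edges[-1] = kym.s[0] + span
    # assign every sample to a segment
    idx = np.clip(np.searchsorted(edges, kym.s, side="right") - 1, 0, len(edges) - 2)
    n_seg = len(edges) - 1
    I_out = np.empty((n_seg, len(kym.t)))
    s_out = np.empty(n_seg)
    counts = np.empty(n_seg, dtype=int)
    for si in range(n_seg):
        members = idx == si
        counts[si] = np.count_nonzero(members)
        I_out[si] = kym.I[members].mean(axis=0)
        s_out[si] = kym.s[members].mean()
    return replace(
        kym,
        s=s_out,
        I=I_out,
        meta={**kym.meta, "segment_edges_um": edges, "segment_counts": counts},
    )


def locate_landmarks(profile, s=None):
    """Focal-adhesion end peaks and mid-fiber valley of an intensity profile.

    The two FA positions are the maxima of the outer 25% of arc length on
    each side; the mSF position is the minimum of the central 50%.  Ties
    break toward the bundle midpoint.  A profile without interior structure
    (monotone or flat) triggers :class:`LandmarkAmbiguityWarning` with
    best-effort positions.  Returns ``(s_fa_left, s_msf, s_fa_right)``.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or len(profile) < 5:
        raise InvalidParameterError("profile must be 1-D with >= 5 samples")
    n = len(profile)
    if s is None:
        s = np.arange(n, dtype=float)
    else:
        s = np.asarray(s, dtype=float)
    mid = 0.5 * (s[0] + s[-1])

    q = max(int(round(0.25 * n)), 1)
    left = slice(0, q)
    right = slice(n - q, n)
    lo = int(round(0.25 * n))
    hi = max(int(round(0.75 * n)), lo + 1)
    center = slice(lo, hi)

    def _pick(idx_slice, values, mode):
        vals = values[idx_slice]
        target = vals.max() if mode == "max" else vals.min()
        cand = np.nonzero(vals == target)[0] + idx_slice.start
        # tie-break toward the bundle midpoint
        return s[cand[np.argmin(np.abs(s[cand] - mid))]]

    fa_left = _pick(left, profile, "max")
    fa_right = _pick(right, profile, "max")
    msf = _pick(center, profile, "min")

    diffs = np.diff(profile)
    monotone = np.all(diffs >= 0) or np.all(diffs <= 0)
    if monotone:
        warnings.warn(
            "profile has no peak/valley structure; returning best-effort "
            "landmark positions",
            LandmarkAmbiguityWarning,
            stacklevel=2,
        )
    return float(fa_left), float(msf), float(fa_right)
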