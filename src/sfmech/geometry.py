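"""Arc geometry: circle fits, chord/sagitta relations, tension balance.

The peripheral fiber appears in fluorescence images as a shallow circular
arc (chord ~36 um, radius ~66 um, sagitta ~2.6 um).  Its radius of
curvature is the observable tied to mechanics through the Bischofs balance
``R = lambda / sigma``.  Fitting is algebraic (Kåsa linear least squares)
followed by geometric Gauss-Newton refinement, which is exact on clean
circles and stable on shallow arcs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateGeometryError, InvalidParameterError

__all__ = [
    "ArcFit",
    "fit_circle_arc",
    "radius_from_chord_sagitta",
    "radius_timeseries",
    "bischofs_tension",
    "bischofs_radius",
    "extract_ridge_points",
    "mask_to_points",
    "read_edge_csv",
    "write_radius_csv",
]


@dataclass(frozen=True)
class ArcFit:
    """Result of a circle fit to arc points (all lengths in um)."""

    center: tuple
    R: float
    rms_residual: float
    n_points: int
    chord: tuple  # (first endpoint, last endpoint)


def _kasa(x, y):
    """Algebraic circle fit: linear least squares on x^2+y^2 = 2ax+2by+c."""
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise DegenerateGeometryError("points are collinear: radius is infinite")
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic fit gave non-positive radius")
    return cx, cy, np.sqrt(r2)


def fit_circle_arc(points) -> ArcFit:
    """Least-squares circle through 2-D points.

    Kåsa initialization refined by geometric (orthogonal-distance) least
    squares.  Rotation/translation invariant; exact on noiseless circles.
    Raises :class:`DegenerateGeometryError` on collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise InvalidParameterError("need at least 3 points of shape (n, 2)")
    x, y = pts[:, 0], pts[:, 1]
    # collinearity: largest triangle area relative to spread
    span = max(np.ptp(x), np.ptp(y), 1e-300)
    xc0, yc0 = x.mean(), y.mean()
    _, s, _ = np.linalg.svd(np.column_stack([x - xc0, y - yc0]), full_matrices=False)
    if s[-1] < 1e-12 * span:
        raise DegenerateGeometryError("points are collinear: radius is infinite")

    cx, cy, r = _kasa(x, y)

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    sol = least_squares(resid, [cx, cy, r], method="lm", xtol=1e-15, ftol=1e-15)
    cx, cy, r = sol.x
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return ArcFit(
        center=(float(cx), float(cy)),
        R=float(abs(r)),
        rms_residual=rms,
        n_points=len(pts),
        chord=(tuple(pts[0]), tuple(pts[-1])),
    )


def radius_from_chord_sagitta(L, h):
    """Circle radius from chord length ``L`` and sagitta ``h``: h/2 + L^2/(8h)."""
    if L <= 0 or h <= 0:
        raise InvalidParameterError("chord and sagitta must be strictly positive")
    return h / 2.0 + L * L / (8.0 * h)


def radius_timeseries(frames, t_grid):
    """Per-frame circle fits; returns (t, R, rms) arrays with NaN markers.

    Frames whose fit is degenerate yield NaN entries (never dropped); if
    every frame is degenerate an error is raised.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if len(frames) != len(t_grid):
        raise InvalidParameterError("frames and t_grid must have equal length")
    R = np.full(len(frames), np.nan)
    rms = np.full(len(frames), np.nan)
    for i, pts in enumerate(frames):
        try:
            fit = fit_circle_arc(pts)
        except (DegenerateGeometryError, InvalidParameterError):
            continue
        R[i] = fit.R
        rms[i] = fit.rms_residual
    if np.all(np.isnan(R)):
        raise DegenerateGeometryError("all frames degenerate: empty series")
    return t_grid, R, rms


def bischofs_tension(R, sigma):
    """Line tension from the force balance: ``lambda = sigma * R`` (nN)."""
    if R <= 0 or sigma <= 0:
        raise InvalidParameterError("R and sigma must be strictly positive")
    return sigma * R


def bischofs_radius(lam, sigma):
    """Arc radius from the force balance: ``R = lambda / sigma`` (um)."""
    if lam <= 0 or sigma <= 0:
        raise InvalidParameterError("lambda and sigma must be strictly positive")
    return lam / sigma


def extract_ridge_points(frame, pixel_size, threshold=None, trim=1.0):
    """Sub-pixel ridge of a bright arc: intensity-weighted centroid per column.

    Convention: continuous um coordinates with the origin at the image's
    lower-left corner and pixel centers at half-integer multiples of
    ``pixel_size``.  Columns whose peak is below ``threshold`` (default:
    10% of the frame maximum) are skipped, and ``trim`` um are dropped at
    each end of the detected span (arc tips are truncated by the endpoint
    cut-off and bias the centroid).  Returns an (n, 2) array of
    (x_um, y_um) points ordered by x.
    """
    img = np.asarray(frame, dtype=float)
    ny, nx = img.shape
    if threshold is None:
        threshold = 0.1 * img.max()
    pts = []
    for j in range(nx):
        col = img[:, j]
        if col.max() < threshold:
            continue
        w = np.clip(col - 0.2 * col.max(), 0.0, None)
        rows = np.arange(ny)
        row_c = np.sum(w * rows) / np.sum(w)
        x = (j + 0.5) * pixel_size
        y = (ny - row_c - 0.5) * pixel_size
        pts.append((x, y))
    pts = np.asarray(pts)
    if trim > 0 and len(pts):
        x = pts[:, 0]
        keep = (x > x.min() + trim) & (x < x.max() - trim)
        if keep.sum() >= 3:
            pts = pts[keep]
    return pts


def mask_to_points(mask, pixel_size):
    """Coordinates (um) of the nonzero pixels of a binary mask.

    Origin at the image's lower-left corner, pixel centers at half-integer
    multiples of ``pixel_size``.
    """
    mask = np.asarray(mask)
    ny = mask.shape[0]
    rows, cols = np.nonzero(mask)
    x = (cols + 0.5) * pixel_size
    y = (ny - rows - 0.5) * pixel_size
    return np.column_stack([x, y])


def read_edge_csv(path):
    """Per-frame edge point sets from a (frame, x_um, y_um) CSV.

    Returns ``(frame_ids, frames)`` with ``frames`` a list of (n, 2)
    arrays ordered by frame id.
    """
    import pandas as pd

    table = pd.read_csv(path)
    required = {"frame", "x_um", "y_um"}
    if not required <= set(table.columns):
        raise InvalidParameterError(
            f"edge CSV needs columns {sorted(required)}, got {list(table.columns)}")
    frames, ids = [], []
    for frame_id, group in table.groupby("frame", sort=True):
        ids.append(frame_id)
        frames.append(group[["x_um", "y_um"]].to_numpy())
    return ids, frames


def write_radius_csv(path, t, R, rms=None):
    """Radius series as a (t_s, R_um, rms_um) CSV."""
    import pandas as pd

    rms = np.full(len(t), np.nan) if rms is None else rms
    pd.DataFrame({"t_s": t, "R_um": R, "rms_um": rms}).to_csv(path, index=False)
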