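"""Downstream functional-imaging quantifications.

dF/F traces, kymographs, static-background subtraction, signal-to-background
ratio and the shear-galvo calibration fit — the standard readouts applied to
props movies.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field
from scipy.ndimage import map_coordinates
from scipy.stats import linregress

from .acquisition import Frame

__all__ = [
    "CalciumTrace",
    "CalibrationFit",
    "delta_f_over_f",
    "kymograph",
    "subtract_static_background",
    "sbr",
    "calibrate_shear",
    "roi_trace",
]


@dataclass
class CalciumTrace:
    """Raw fluorescence with its baseline and relative change dF/F."""

    time: np.ndarray
    F: np.ndarray
    F0: float
    dFF: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.dFF = np.asarray(self.dFF, dtype=float)
        if not (len(self.time) == len(self.F) == len(self.dFF)):
            raise ValueError("time, F and dFF must have matching lengths")
        if self.F0 <= 0:
            raise ValueError("F0 must be > 0")


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line through (command, shift) calibration points."""

    slope: float
    intercept: float
    r_squared: float
    max_residual: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("calibration needs at least 3 points")


def _frames_to_array(frames) -> np.ndarray:
    if isinstance(frames, np.ndarray):
        arr = frames
    else:
        arr = np.stack([f.data if isinstance(f, Frame) else np.asarray(f) for f in frames])
    if arr.ndim != 3:
        raise ValueError("expected a (t, rows, cols) movie")
    return arr.astype(float)


def delta_f_over_f(
    time,
    F,
    baseline_method: str = "percentile",
    percentile: float = 20.0,
    window: tuple[float, float] | None = None,
) -> CalciumTrace:
    """Relative fluorescence change (F − F0)/F0.

    The baseline F0 is either the ``percentile``-th percentile of F
    (default 20) or the mean over a stated time ``window`` (seconds,
    inclusive).  dF/F is invariant to global intensity rescaling of F.
    """
    time = np.asarray(time, dtype=float)
    F = np.asarray(F, dtype=float)
    if baseline_method == "percentile":
        f0 = float(np.percentile(F, percentile))
    elif baseline_method == "window":
        if window is None:
            raise ValueError("window baseline requires window=(t0, t1)")
        t0, t1 = window
        if t0 < time[0] - 1e-12 or t1 > time[-1] + 1e-12:
            raise ValueError("baseline window outside the trace time range")
        sel = (time >= t0) & (time <= t1)
        if not sel.any():
            raise ValueError("baseline window contains no samples")
        f0 = float(F[sel].mean())
    else:
        raise ValueError("baseline_method must be 'percentile' or 'window'")
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0:g} is not positive")
    return CalciumTrace(time=time, F=F, F0=f0, dFF=(F - f0) / f0)


def roi_trace(frames, mask: np.ndarray) -> np.ndarray:
    """Mean intensity inside a boolean ROI mask, per frame."""
    arr = _frames_to_array(frames)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape[1:]:
        raise ValueError("ROI mask shape does not match the frames")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return arr[:, mask].mean(axis=1)


def kymograph(frames, polyline, line_width_px: float = 1.0, step_px: float = 1.0) -> np.ndarray:
    """Position-vs-time image sampled along a polyline through a movie.

    ``polyline`` is a sequence of ≥ 2 (row, col) pixel vertices; intensity is
    linearly interpolated along the line (one sample per ``step_px``) and
    averaged across ``line_width_px`` perpendicular offsets.  Output shape is
    (n_samples, n_frames).
    """
    arr = _frames_to_array(frames)
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be >= 2 (row, col) vertices")
    nr, nc = arr.shape[1:]
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > nr - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > nc - 1):
        raise ValueError("polyline extends outside the frame bounds")
    # densely sample the polyline
    segs = []
    for p, q in zip(pts[:-1], pts[1:]):
        L = float(np.hypot(*(q - p)))
        n = max(2, int(np.ceil(L / step_px)) + 1)
        t = np.linspace(0, 1, n)[:-1]  # endpoint re-added by the next segment
        segs.append(p[None, :] + t[:, None] * (q - p)[None, :])
    segs.append(pts[-1][None, :])
    path = np.vstack(segs)
    # unit normals per sample (from local tangent)
    tang = np.gradient(path, axis=0)
    norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    nlen = np.linalg.norm(norm, axis=1, keepdims=True)
    norm = np.divide(norm, nlen, out=np.zeros_like(norm), where=nlen > 0)
    n_off = max(1, int(round(line_width_px)))
    offs = np.linspace(-(line_width_px - 1) / 2.0, (line_width_px - 1) / 2.0, n_off)
    ky = np.zeros((path.shape[0], arr.shape[0]))
    for t_idx in range(arr.shape[0]):
        acc = np.zeros(path.shape[0])
        for o in offs:
            coords = (path + o * norm).T  # (2, n_samples)
            acc += map_coordinates(arr[t_idx], coords, order=1, mode="nearest")
        ky[:, t_idx] = acc / n_off
    return ky


def subtract_static_background(
    frames, method: str = "temporal_median", clamp: bool = True
):
    """Remove the per-pixel static component of a movie.

    ``method`` is ``temporal_median`` or ``temporal_min``; output is clamped
    at zero by default (display-oriented), pass ``clamp=False`` for the raw
    signed residual.  Returns an array of the same (t, rows, cols) shape.
    """
    arr = _frames_to_array(frames)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 frames to estimate a static background")
    if method == "temporal_median":
        static = np.median(arr, axis=0)
    elif method == "temporal_min":
        static = arr.min(axis=0)
    else:
        raise ValueError("method must be 'temporal_median' or 'temporal_min'")
    out = arr - static[None]
    if clamp:
        out = np.clip(out, 0.0, None)
    return out


def sbr(frame, fg_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """Signal-to-background ratio: mean(frame[fg]) / mean(frame[bg])."""
    data = frame.data if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    fg = np.asarray(fg_mask, dtype=bool)
    bg = np.asarray(bg_mask, dtype=bool)
    if not fg.any() or not bg.any():
        raise ValueError("foreground and background masks must be nonempty")
    if (fg & bg).any():
        raise ValueError("foreground and background masks must be disjoint")
    denom = float(data[bg].mean())
    if denom == 0:
        raise ValueError("background mean is zero; SBR undefined")
    return float(data[fg].mean()) / denom


def calibrate_shear(commands, measured_shifts_um) -> CalibrationFit:
    """OLS line through shear-galvo calibration points with residual check.

    ``commands`` are the drive values (e.g. volts), ``measured_shifts_um``
    the observed image shifts; the fit reports slope (µm per command unit),
    intercept, r² and the largest absolute residual as a linearity
    assessment.
    """
    x = np.asarray(commands, dtype=float)
    y = np.asarray(measured_shifts_um, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("commands and shifts must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("calibration needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("commands are all equal: rank-deficient calibration")
    res = linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        max_residual=float(np.max(np.abs(resid))),
        n_points=int(x.size),
    )
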