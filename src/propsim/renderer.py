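"""Digital shear-warp slab and curved-surface projection of 3-D volumes.

This is the post-hoc counterpart of the optical simulator (the "graphics
software" analogy): planes are masked by slab membership, sheared along x by
−z·tan ψ (so a point at (x, z) lands at x − z·tan ψ, matching the optical
convention) and reduced along z.  The final 2-D warp stage of the shear-warp
factorisation is a global scale that is omitted here, as frames are kept in
sample-space µm throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import shift as nd_shift

from .acquisition import Frame
from .geometry import SlabSpec, SurfaceSpec, ViewSpec
from .phantoms import Volume

__all__ = [
    "slab_project",
    "curved_project",
    "compare_frames",
    "unshear_frame",
    "FrameComparison",
]

_REDUCERS = ("sum", "max", "mean")


def _slab_weights(z: np.ndarray, slab: SlabSpec) -> np.ndarray:
    """Per-plane weights: hard top-hat (closed interval, the oracle
    definition) or a Gaussian window of matched FWHM."""
    if slab.weighting == "hard":
        return ((z >= slab.z_lo) & (z <= slab.z_hi)).astype(float)
    sigma = slab.z_depth / 2.355  # FWHM-matched
    if sigma == 0:
        return (z == slab.z_center).astype(float)
    return np.exp(-0.5 * ((z - slab.z_center) / sigma) ** 2)


def slab_project(
    volume: Volume,
    slab: SlabSpec,
    view: ViewSpec,
    reducer: str = "sum",
    x_range: tuple[float, int] | None = None,
) -> Frame:
    """Project the slab under viewing angle ψ by per-plane shear + reduce.

    ``x_range = (origin_µm, n_cols)`` widens/narrows the output x-grid
    (default: the volume's own x-grid); useful at large |ψ| where sheared
    content leaves the volume footprint.  Output frame axes are ("y", "x").
    """
    if reducer not in _REDUCERS:
        raise ValueError(f"reducer must be one of {_REDUCERS}")
    dz, dy, dx = volume.voxel_size
    z = volume.z_coords()
    w = _slab_weights(z, slab)
    if x_range is None:
        x0, n_out = volume.origin[2], volume.shape[2]
    else:
        x0, n_out = x_range
    sel = np.nonzero(w > 1e-12)[0]
    ny = volume.shape[1]
    if sel.size == 0:
        warnings.warn("empty slab: no plane centres inside the selection")
        return Frame(np.zeros((ny, n_out)), pixel_size=dx, axes="yx",
                     origin=(volume.origin[1], x0), meta={"slab": slab, "view": view})
    planes = np.zeros((sel.size, ny, n_out))
    # base offset between output grid and volume grid, in pixels
    base = (x0 - volume.origin[2]) / dx
    for i, k in enumerate(sel):
        # sample volume plane at x_out + z·tanψ  (content moves to x − z·tanψ)
        off = z[k] * view.tan_psi / dx + base
        planes[i] = _shift_into(volume.data[k].astype(float), off, n_out)
    wsel = w[sel]
    if reducer == "sum":
        out = np.tensordot(wsel, planes, axes=(0, 0))
    elif reducer == "mean":
        out = np.tensordot(wsel, planes, axes=(0, 0)) / wsel.sum()
    else:  # max
        out = (planes * wsel[:, None, None]).max(axis=0)
    return Frame(out, pixel_size=dx, axes="yx", origin=(volume.origin[1], x0),
                 meta={"slab": slab, "view": view, "reducer": reducer})


def _shift_into(plane: np.ndarray, off: float, n_out: int) -> np.ndarray:
    """Resample a (ny, nx) plane onto a wider x-grid shifted by ``off`` px."""
    ny, nx = plane.shape
    xi = np.arange(n_out) + off
    i0 = np.floor(xi).astype(int)
    f = xi - i0
    out = np.zeros((ny, n_out))
    ok0 = (i0 >= 0) & (i0 < nx)
    ok1 = (i0 + 1 >= 0) & (i0 + 1 < nx)
    out[:, ok0] += plane[:, i0[ok0]] * (1 - f[ok0])
    out[:, ok1] += plane[:, i0[ok1] + 1] * f[ok1]
    return out


def curved_project(
    volume: Volume,
    surface: SurfaceSpec,
    reducer: str = "sum",
) -> Frame:
    """Planar map of a curved layer: reduce over z ∈ z*(x) ± half_width.

    The output x-coordinate is the untransformed x.  With half_width = 0 a
    single z-interpolated sample is taken at z*(x); otherwise plane centres
    inside the closed band are reduced, so a flat surface reproduces
    :func:`slab_project` at ψ = 0 exactly.
    """
    if reducer not in _REDUCERS:
        raise ValueError(f"reducer must be one of {_REDUCERS}")
    dz, dy, dx = volume.voxel_size
    xs = volume.x_coords()
    if xs[0] < surface.x_grid[0] - 1e-9 or xs[-1] > surface.x_grid[-1] + 1e-9:
        warnings.warn("surface does not cover the volume x-range; output restricted")
        keep = (xs >= surface.x_grid[0]) & (xs <= surface.x_grid[-1])
    else:
        keep = np.ones(xs.size, dtype=bool)
    z_star = np.asarray(surface.z(xs))
    (z_lo_v, z_hi_v) = volume.extent()[0]
    if np.any(z_star[keep] < z_lo_v - surface.half_width) or np.any(
        z_star[keep] > z_hi_v + surface.half_width
    ):
        raise ValueError("surface lies outside the volume z-range")
    zg = volume.z_coords()
    ny = volume.shape[1]
    if surface.half_width == 0:
        zi = (z_star - volume.origin[0]) / dz
        i0 = np.clip(np.floor(zi).astype(int), 0, volume.shape[0] - 2)
        f = zi - i0
        cols = np.arange(xs.size)
        out = (volume.data[i0, :, cols] * (1 - f[:, None])
               + volume.data[i0 + 1, :, cols] * f[:, None]).T
    else:
        w = (np.abs(zg[:, None] - z_star[None, :]) <= surface.half_width).astype(float)
        if reducer == "sum":
            out = np.einsum("zx,zyx->yx", w, volume.data.astype(float))
        elif reducer == "mean":
            n = np.maximum(w.sum(axis=0), 1e-300)
            out = np.einsum("zx,zyx->yx", w, volume.data.astype(float)) / n[None, :]
        else:
            masked = volume.data.astype(float) * w[:, None, :]
            out = masked.max(axis=0)
    out = out * keep[None, :]
    return Frame(out, pixel_size=dx, axes="yx",
                 origin=(volume.origin[1], volume.origin[2]),
                 meta={"surface": surface, "reducer": reducer})


def unshear_frame(frame: Frame, volume_like: Volume, view: ViewSpec) -> Frame:
    """Digitally undo the renderer's shear for a frame of a single plane set.

    Only meaningful as a consistency check on content at a known height
    (shifts every row set back by +z̄·tan ψ using the slab centre stored in
    ``meta``)."""
    slab: SlabSpec = frame.meta["slab"]
    off = slab.z_center * view.tan_psi / frame.pixel_size
    data = nd_shift(frame.data.astype(float), (0.0, off), order=1, mode="constant",
                    cval=0.0, prefilter=False)
    return Frame(data, frame.pixel_size, frame.axes, frame.origin,
                 {**frame.meta, "unsheared": True})


@dataclass(frozen=True)
class FrameComparison:
    nrmse: float
    pearson: float
    centroid_offsets_px: tuple[float, ...] = ()

    @property
    def max_centroid_offset_px(self) -> float:
        return max(self.centroid_offsets_px) if self.centroid_offsets_px else float("nan")


def _local_centroid(data: np.ndarray, row: float, col: float, half: int) -> tuple[float, float]:
    r0 = max(0, int(round(row)) - half)
    r1 = min(data.shape[0], int(round(row)) + half + 1)
    c0 = max(0, int(round(col)) - half)
    c1 = min(data.shape[1], int(round(col)) + half + 1)
    win = data[r0:r1, c0:c1]
    tot = win.sum()
    if tot <= 0:
        return (float(row), float(col))
    ri = np.arange(r0, r1)
    ci = np.arange(c0, c1)
    return (float((win.sum(1) * ri).sum() / tot), float((win.sum(0) * ci).sum() / tot))


def compare_frames(
    a: Frame,
    b: Frame,
    spots: list[tuple[float, float]] | None = None,
    window_px: int = 4,
) -> FrameComparison:
    """Agreement metrics between two frames on a common grid.

    If the two frames carry transposed axes tags (e.g. a simulator "uy"
    frame against a renderer "yx" frame), ``b`` is transposed before the
    comparison.  ``spots`` are approximate (row_px, col_px) positions in
    ``a``'s orientation; the offset of the local intensity centroid between
    the two frames is reported per spot in pixels.
    """
    def _canon(axes: str) -> str:
        return axes.replace("u", "x")  # "u" is the sheared x row coordinate

    if a.axes and b.axes and _canon(a.axes) == _canon(b.axes)[::-1]:
        b = b.transposed()
    if a.data.shape != b.data.shape:
        raise ValueError(f"frame shapes differ: {a.data.shape} vs {b.data.shape}")
    da, db = a.data.astype(float), b.data.astype(float)
    rng = float(da.max() - da.min())
    rmse = float(np.sqrt(np.mean((da - db) ** 2)))
    nrmse = rmse / rng if rng > 0 else (0.0 if rmse == 0 else float("inf"))
    sa, sb = da.ravel() - da.mean(), db.ravel() - db.mean()
    denom = float(np.sqrt((sa**2).sum() * (sb**2).sum()))
    pearson = float((sa * sb).sum() / denom) if denom > 0 else 1.0
    offsets = []
    if spots:
        for row, col in spots:
            ca = _local_centroid(da, row, col, window_px)
            cb = _local_centroid(db, row, col, window_px)
            offsets.append(float(np.hypot(ca[0] - cb[0], ca[1] - cb[1])))
    return FrameComparison(nrmse=nrmse, pearson=pearson,
                           centroid_offsets_px=tuple(offsets))
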