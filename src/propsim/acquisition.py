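"""Forward model of the props camera.

A single projection frame is integrated by sweeping the tilted sheet across
the sample, shearing the image on the camera by g(s) = r·s + q(s) + b, and
masking rows with the synchronised rolling shutter.  Frames are reported on
a sample-space row grid: the camera row u is divided by the shear rate r
(the global "warp" scale of the shear-warp factorisation), so the frame row
coordinate of a point at (x, z) is x − z·tan ψ and optical frames live on
the same grid as the digital renderer's.

The sweep is discretised at one step per row-pixel of travel by default;
with linear interpolation this makes the accumulated sweep an exact
partition of unity, so the total frame intensity equals the total volume
intensity for a full-open shutter (interior structures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import (
    OpticsConfig,
    ShearWaveform,
    ShutterConfig,
    SweepConfig,
    shutter_row_speed,
)
from .phantoms import TimeLapse, Volume

__all__ = [
    "AcquisitionConfig",
    "Frame",
    "NoiseModel",
    "default_sweep",
    "full_open_shutter",
    "simulate_projection",
    "simulate_projection_sequence",
    "simulate_stack",
    "apply_noise",
]


@dataclass
class Frame:
    """A single 2-D projection image with pixel size and provenance.

    ``axes`` records the physical meaning of (rows, cols): ``"uy"`` for
    simulator frames (row = sample-space sheared x, col = y) and ``"yx"``
    for renderer frames.  ``origin`` is the physical µm coordinate of pixel
    (0, 0).
    """

    data: np.ndarray
    pixel_size: float = 1.0
    axes: str = "uy"
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("Frame data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Frame data must be finite")

    def transposed(self) -> "Frame":
        return Frame(
            self.data.T,
            self.pixel_size,
            self.axes[::-1],
            (self.origin[1], self.origin[0]),
            dict(self.meta),
        )

    def centroid(self) -> tuple[float, float]:
        """Intensity-weighted centroid (row_µm, col_µm) incl. origin."""
        tot = float(self.data.sum())
        if tot == 0:
            raise ValueError("cannot take the centroid of an all-zero frame")
        ri = np.arange(self.data.shape[0])
        ci = np.arange(self.data.shape[1])
        r = float((self.data.sum(axis=1) * ri).sum() / tot)
        c = float((self.data.sum(axis=0) * ci).sum() / tot)
        return (self.origin[0] + r * self.pixel_size, self.origin[1] + c * self.pixel_size)


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise: Poisson(scale·I)/scale + N(0, σ_read) + offset."""

    photon_scale: float = 1.0
    read_sigma: float = 0.0
    offset: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")


@dataclass(frozen=True)
class AcquisitionConfig:
    optics: OpticsConfig
    sweep: SweepConfig
    shear: ShearWaveform
    shutter: ShutterConfig
    noise: NoiseModel | None = None
    frame_shape: tuple[int, int] | None = None
    row_origin: float | None = None  # µm coordinate of frame row 0


def default_sweep(
    volume: Volume, optics: OpticsConfig, duration: float = 1.0,
    step: float | None = None, margin: float = 2.0,
) -> SweepConfig:
    """Sweep covering every illumination position of the volume.

    A point (x, z) is illuminated at s = x − z·tan φ, so the sweep spans
    [x_min − z_max·tan φ − margin, x_max + margin] with one step per
    row-pixel of travel (``step`` defaults to the pixel pitch), which makes
    the discretised sweep an exact partition of unity.
    """
    if step is None:
        step = optics.pixel_pitch
    (z0, z1), _, (x0, x1) = volume.extent()
    s_lo = x0 - max(z1, 0.0) * optics.tan_phi - margin
    s_hi = x1 - min(z0, 0.0) * optics.tan_phi + margin
    n = int(np.ceil((s_hi - s_lo) / step)) + 1
    return SweepConfig(s_start=s_lo, s_end=s_lo + (n - 1) * step, n_steps=n,
                       sweep_duration=duration)


def full_open_shutter() -> ShutterConfig:
    """Shutter wide enough to never clip any row (conventional projection)."""
    return ShutterConfig(width_W=1e9, center_c0=0.0, delay_tau=0.0)


def _column_map(volume: Volume, acq: AcquisitionConfig, n_cols: int):
    """Map volume y-columns onto frame columns (linear splat weights)."""
    pitch = acq.optics.pixel_pitch
    yc = volume.y_coords()
    cf = yc / pitch
    c0 = np.floor(cf).astype(int)
    w1 = cf - c0
    return c0, w1


def simulate_projection(volume: Volume, acq: AcquisitionConfig) -> Frame:
    """Integrate one props frame: sweep, shear, rolling shutter, noise.

    For every sweep step s the oblique sheet plane {(s + t·sin φ, y,
    t·cos φ)} is sampled by trilinear interpolation (Gaussian-weighted
    across the sheet when sheet_sigma > 0), mapped to camera row
    u = t + g(s), masked by the shutter window |u − u_sh(s)| ≤ W/2 with
    u_sh(s) = r·s + b + c0 + v_u·τ, and accumulated into the frame at the
    sample-space row (u − b)/r.  Noise-free output is linear in the volume.
    """
    optics, sweep, shear, shutter = acq.optics, acq.sweep, acq.shear, acq.shutter
    if not shutter.synchronized:
        raise ValueError("simulate_projection models synchronized shutters only")
    dz, dy, dx = volume.voxel_size
    nz, ny, nx = volume.shape
    pitch = optics.pixel_pitch

    if acq.frame_shape is None:
        n_rows, n_cols = nx, ny
    else:
        n_rows, n_cols = acq.frame_shape
    row0 = volume.origin[2] if acq.row_origin is None else acq.row_origin

    # in-plane parameter t chosen so sheet samples land on volume z-planes
    z_planes = volume.z_coords()
    t_grid = z_planes / optics.cos_phi
    v_u = shutter_row_speed(shear, sweep)
    band = shutter.center_c0 + v_u * shutter.delay_tau

    # across-sheet Gaussian sampling (1/e half thickness sheet_sigma)
    if optics.sheet_sigma > 0:
        step_d = 0.5 * min(dz, dx)
        d_off = np.arange(-3 * optics.sheet_sigma, 3 * optics.sheet_sigma + step_d / 2, step_d)
        d_w = np.exp(-((d_off / optics.sheet_sigma) ** 2))
        d_w /= d_w.sum()
    else:
        d_off = np.array([0.0])
        d_w = np.array([1.0])

    s_grid = sweep.s_grid()
    scale = sweep.delta_s / dx
    acc = np.zeros((n_rows, ny), dtype=np.float64)
    y_idx = np.arange(ny, dtype=float)

    clipped = False
    for s in s_grid:
        qs = float(np.asarray(shear.q(s)))
        # shutter residual depends on the in-plane coordinate t only
        resid = t_grid + qs - band
        mask = np.abs(resid) <= shutter.width_W / 2.0
        if not mask.any():
            continue
        t_m = t_grid[mask]
        # sample-space row coordinate (u - b)/r
        rows_um = s + (t_m + qs) / shear.rate_r
        rf = (rows_um - row0) / pitch
        r0 = np.floor(rf).astype(int)
        w1 = rf - r0
        inside = (r0 >= -1) & (r0 < n_rows)
        plane = np.zeros((t_m.size, ny), dtype=np.float64)
        for d, wd in zip(d_off, d_w):
            zc = (t_m * optics.cos_phi - d * optics.sin_phi - volume.origin[0]) / dz
            xc = (s + t_m * optics.sin_phi + d * optics.cos_phi - volume.origin[2]) / dx
            coords = np.empty((3, t_m.size, ny))
            coords[0] = zc[:, None]
            coords[1] = y_idx[None, :]
            coords[2] = xc[:, None]
            plane += wd * map_coordinates(
                volume.data, coords, order=1, mode="constant", cval=0.0
            )
        vals = plane * scale
        if not inside.all() and float(np.abs(vals[~inside]).sum()) > 1e-12:
            clipped = True
        lo_ok = (r0 >= 0) & (r0 < n_rows)
        hi_ok = (r0 + 1 >= 0) & (r0 + 1 < n_rows)
        if lo_ok.any():
            np.add.at(acc, r0[lo_ok], vals[lo_ok] * (1.0 - w1[lo_ok, None]))
        if hi_ok.any():
            np.add.at(acc, r0[hi_ok] + 1, vals[hi_ok] * w1[hi_ok, None])
    if clipped:
        warnings.warn("sheared image extends beyond the frame rows; cropped")

    # map volume y-columns onto frame columns
    if n_cols == ny and abs(dy - pitch) < 1e-12 and abs(volume.origin[1]) < 1e-12:
        frame = acc
    else:
        frame = np.zeros((n_rows, n_cols), dtype=np.float64)
        c0, w1 = _column_map(volume, acq, n_cols)
        for j in range(ny):
            if 0 <= c0[j] < n_cols:
                frame[:, c0[j]] += acc[:, j] * (1.0 - w1[j])
            if 0 <= c0[j] + 1 < n_cols:
                frame[:, c0[j] + 1] += acc[:, j] * w1[j]
    if not np.any(frame):
        warnings.warn("empty selection: shutter window never overlapped the image rows")
    out = Frame(frame, pixel_size=pitch, axes="uy", origin=(row0, volume.origin[1]),
                meta={"acq": acq})
    if acq.noise is not None:
        out = apply_noise(out, acq.noise)
    return out


def simulate_projection_sequence(
    movie: TimeLapse,
    acq_per_frame: AcquisitionConfig | list[AcquisitionConfig],
) -> list[Frame]:
    """Simulate one props frame per movie time point.

    ``acq_per_frame`` is a single config (constant acquisition) or a list of
    length n_frames; alternating-delay lists interleave two slab series
    without any mechanical motion.  Each output frame is tagged with the
    config that produced it.
    """
    if isinstance(acq_per_frame, AcquisitionConfig):
        configs = [acq_per_frame] * movie.n_frames
    else:
        configs = list(acq_per_frame)
        if len(configs) != movie.n_frames:
            raise ValueError(
                f"got {len(configs)} configs for {movie.n_frames} movie frames"
            )
    frames = []
    for t, acq in enumerate(configs):
        f = simulate_projection(movie.volume(t), acq)
        f.meta["t_index"] = t
        f.meta["time_s"] = t * movie.frame_interval
        frames.append(f)
    return frames


def simulate_stack(volume: Volume, acq: AcquisitionConfig, dz_step: float) -> TimeLapse:
    """Conventional plane-by-plane z-stack (no shear, no shutter).

    Plane k is the sheet-weighted image at fixed z = k·dz_step; with an
    ideally thin sheet this is the interpolated z-plane of the volume, and
    the plane weights are normalised so a dz-matched stack sums to the
    top-down full projection.
    """
    if dz_step <= 0:
        raise ValueError("dz_step must be > 0")
    optics = acq.optics
    dz = volume.voxel_size[0]
    n_planes = int(np.floor(optics.z_max / dz_step)) + 1
    zs = np.arange(n_planes) * dz_step
    nz, ny, nx = volume.shape
    planes = np.zeros((n_planes, ny, nx), dtype=np.float32)
    sigma_z = optics.sheet_sigma / optics.cos_phi if optics.sheet_sigma > 0 else 0.0
    z_grid = volume.z_coords()
    for k, z in enumerate(zs):
        if sigma_z == 0:
            zi = (z - volume.origin[0]) / dz
            i0 = int(np.floor(zi))
            f = zi - i0
            p = np.zeros((ny, nx))
            if 0 <= i0 < nz:
                p += (1 - f) * volume.data[i0]
            if 0 <= i0 + 1 < nz:
                p += f * volume.data[i0 + 1]
            planes[k] = p
        else:
            w = np.exp(-0.5 * ((z_grid - z) / sigma_z) ** 2)
            tot = w.sum()
            if tot > 0:
                planes[k] = np.tensordot(w / tot, volume.data, axes=(0, 0))
    return TimeLapse(
        planes,
        frame_interval=1.0,
        voxel_size=(dz_step,) + tuple(volume.voxel_size[1:]),
        meta={"kind": "z-stack", "dz_step": dz_step},
    )


def apply_noise(frame: Frame, model: NoiseModel) -> Frame:
    """Seeded shot + read noise: Poisson(scale·I)/scale + N(0, σ) + offset."""
    rng = np.random.default_rng(model.seed)
    counts = rng.poisson(np.clip(frame.data, 0, None) * model.photon_scale)
    data = counts.astype(np.float64) / model.photon_scale
    if model.read_sigma > 0:
        data = data + rng.normal(0.0, model.read_sigma, frame.data.shape)
    data = data + model.offset
    return Frame(data, frame.pixel_size, frame.axes, frame.origin,
                 {**frame.meta, "noise": model})
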