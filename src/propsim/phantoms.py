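"""Seeded synthetic phantoms with ground truth for parameter recovery.

Every input the simulator and analyses need can be generated here: Gaussian
bead fields, vessel-like curvilinear tubes, a cylindrically curved
fluorescent shell decorated with surface blobs (embryo-surface analogue),
two axially separated layers of soma-like cells with calcium transients, and
a depth-dependent scattering-haze surrogate.  All generators are
deterministic for a fixed seed and return the realised ground-truth tables
alongside the volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geometry import SurfaceSpec

__all__ = [
    "Volume",
    "TimeLapse",
    "TwoLayerSpec",
    "make_bead_phantom",
    "make_vessel_phantom",
    "make_shell_phantom",
    "make_calcium_phantom",
    "add_haze",
    "calcium_kernel",
    "peak_dff",
]


@dataclass
class Volume:
    """3-D nonnegative intensity grid with physical voxel sizes.

    ``data`` is indexed (z, y, x); ``voxel_size`` is (dz, dy, dx) in µm and
    ``origin`` the physical coordinate of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3-D (z, y, x)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data must be finite")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("Volume data must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def z_coords(self) -> np.ndarray:
        return self.origin[0] + self.voxel_size[0] * np.arange(self.shape[0])

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + self.voxel_size[1] * np.arange(self.shape[1])

    def x_coords(self) -> np.ndarray:
        return self.origin[2] + self.voxel_size[2] * np.arange(self.shape[2])

    def extent(self) -> tuple[tuple[float, float], ...]:
        """((z0, z1), (y0, y1), (x0, x1)) physical extents of voxel centres."""
        return tuple(
            (o, o + v * (n - 1))
            for o, v, n in zip(self.origin, self.voxel_size, self.shape)
        )

    def total(self) -> float:
        return float(self.data.sum())


@dataclass
class TimeLapse:
    """Sequence of equally shaped frames or volumes; first axis is time."""

    data: np.ndarray
    frame_interval: float = 1.0
    voxel_size: tuple[float, ...] = (1.0, 1.0, 1.0)
    origin: tuple[float, ...] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim < 3:
            raise ValueError("TimeLapse data must be at least (t, rows, cols)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def times(self) -> np.ndarray:
        return self.frame_interval * np.arange(self.n_frames)

    def volume(self, t: int) -> Volume:
        if self.data.ndim != 4:
            raise ValueError("TimeLapse frames are not 3-D volumes")
        return Volume(self.data[t], tuple(self.voxel_size), tuple(self.origin))


# ---------------------------------------------------------------------------
# beads

def _render_gaussian_blobs(
    data: np.ndarray,
    voxel_size: tuple[float, float, float],
    origin: tuple[float, float, float],
    table: pd.DataFrame,
) -> None:
    """Add isotropic (or z-anisotropic) Gaussian blobs in place.

    Table columns: x, y, z (µm), amplitude, sigma; optional sigma_z.
    """
    dz, dy, dx = voxel_size
    nz, ny, nx = data.shape
    for row in table.itertuples(index=False):
        sig_xy = float(row.sigma)
        sig_z = float(getattr(row, "sigma_z", sig_xy))
        amp = float(row.amplitude)
        # 4-sigma support window per axis, clipped to the grid
        ks = []
        for c, o, d, n, sig in (
            (row.z, origin[0], dz, nz, sig_z),
            (row.y, origin[1], dy, ny, sig_xy),
            (row.x, origin[2], dx, nx, sig_xy),
        ):
            ci = (float(c) - o) / d
            half = max(1, int(np.ceil(4.0 * sig / d)))
            i0 = max(0, int(np.floor(ci)) - half)
            i1 = min(n, int(np.ceil(ci)) + half + 1)
            idx = np.arange(i0, i1)
            prof = np.exp(-0.5 * ((idx - ci) * d / sig) ** 2)
            ks.append((i0, i1, prof))
        (z0, z1, pz), (y0, y1, py), (x0, x1, px) = ks
        data[z0:z1, y0:y1, x0:x1] += amp * pz[:, None, None] * py[None, :, None] * px[None, None, :]


def make_bead_phantom(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    beads: pd.DataFrame | None = None,
    n: int | None = None,
    seed: int | None = None,
    amplitude: float = 100.0,
    sigma: float = 1.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[Volume, pd.DataFrame]:
    """Render Gaussian beads into a volume and return the realised table.

    Either pass an explicit ``beads`` table (columns x, y, z, amplitude,
    sigma, optional sigma_z, µm/photons) or ``n`` and ``seed`` for uniformly
    random placement with a 4σ margin from the bounds.
    """
    if beads is None:
        if n is None:
            raise ValueError("pass either a beads table or n (+ seed)")
        rng = np.random.default_rng(seed)
        ext = [
            (o + 4 * sigma, o + v * (s - 1) - 4 * sigma)
            for o, v, s in zip(origin, voxel_size, shape)
        ]
        beads = pd.DataFrame(
            {
                "x": rng.uniform(*ext[2], size=n),
                "y": rng.uniform(*ext[1], size=n),
                "z": rng.uniform(*ext[0], size=n),
                "amplitude": np.full(n, float(amplitude)),
                "sigma": np.full(n, float(sigma)),
            }
        )
    else:
        beads = beads.copy().reset_index(drop=True)
    if np.any(beads["sigma"].to_numpy() < 0.5 * min(voxel_size)):
        raise ValueError("bead sigma must be >= 0.5 voxel")
    ext = [(o, o + v * (s - 1)) for o, v, s in zip(origin, voxel_size, shape)]
    bad = beads[
        (beads.z < ext[0][0]) | (beads.z > ext[0][1])
        | (beads.y < ext[1][0]) | (beads.y > ext[1][1])
        | (beads.x < ext[2][0]) | (beads.x > ext[2][1])
    ]
    if len(bad):
        raise ValueError(f"beads outside volume bounds at rows {list(bad.index)}")
    data = np.zeros(shape, dtype=np.float32)
    _render_gaussian_blobs(data, voxel_size, origin, beads)
    return Volume(data, voxel_size, origin), beads


# ---------------------------------------------------------------------------
# vessels

def make_vessel_phantom(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_vessels: int = 10,
    seed: int | None = None,
    radius_range: tuple[float, float] = (2.0, 4.0),
    amplitude: float = 100.0,
    z_range: tuple[float, float] | None = None,
) -> Volume:
    """Random smooth tubes spanning the volume (vasculature stand-in).

    Each vessel is a cubic-spline polyline through random control points,
    rasterised as a tube of radius 2–4 µm with a soft parabolic cross-section.
    Tubes are confined to ``z_range`` (default: the full z-extent).
    """
    if n_vessels < 1:
        raise ValueError("n_vessels must be >= 1")
    from scipy.interpolate import CubicSpline

    rng = np.random.default_rng(seed)
    dz, dy, dx = voxel_size
    nz, ny, nx = shape
    lz, lyy, lx = dz * (nz - 1), dy * (ny - 1), dx * (nx - 1)
    if z_range is None:
        z_range = (0.0, lz)
    data = np.zeros(shape, dtype=np.float32)
    offs_cache: dict[int, tuple[np.ndarray, ...]] = {}
    for _ in range(n_vessels):
        r = rng.uniform(*radius_range)
        n_ctrl = 5
        xc = np.linspace(0.0, lx, n_ctrl)
        yc = rng.uniform(0.1 * lyy, 0.9 * lyy, n_ctrl)
        zc = rng.uniform(z_range[0] + r, z_range[1] - r, n_ctrl)
        sy, sz = CubicSpline(xc, yc), CubicSpline(xc, zc)
        xs = np.arange(0.0, lx, 0.5 * min(voxel_size))
        ys, zs = sy(xs), np.clip(sz(xs), z_range[0] + r, z_range[1] - r)
        # precompute sphere-offset kernel for this radius
        hz, hy, hx = (int(np.ceil(r / d)) for d in (dz, dy, dx))
        key = (hz, hy, hx)
        if key not in offs_cache:
            gz, gy, gx = np.mgrid[-hz : hz + 1, -hy : hy + 1, -hx : hx + 1]
            offs_cache[key] = (gz, gy, gx)
        gz, gy, gx = offs_cache[key]
        for px, py, pz in zip(xs, ys, zs):
            iz, iy, ix = (
                int(round(pz / dz)),
                int(round(py / dy)),
                int(round(px / dx)),
            )
            z0, z1 = max(0, iz - hz), min(nz, iz + hz + 1)
            y0, y1 = max(0, iy - hy), min(ny, iy + hy + 1)
            x0, x1 = max(0, ix - hx), min(nx, ix + hx + 1)
            if z0 >= z1 or y0 >= y1 or x0 >= x1:
                continue
            zz = (np.arange(z0, z1) * dz - pz)[:, None, None]
            yy = (np.arange(y0, y1) * dy - py)[None, :, None]
            xx = (np.arange(x0, x1) * dx - px)[None, None, :]
            d2 = zz**2 + yy**2 + xx**2
            prof = amplitude * np.clip(1.0 - d2 / r**2, 0.0, None)
            np.maximum(data[z0:z1, y0:y1, x0:x1], prof, out=data[z0:z1, y0:y1, x0:x1])
    return Volume(data, voxel_size)


# ---------------------------------------------------------------------------
# curved shell

def make_shell_phantom(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    arc_params: dict | None = None,
    n_blobs: int = 10,
    seed: int | None = None,
    thickness: float = 2.0,
    shell_amplitude: float = 10.0,
    blob_amplitude: float = 300.0,
    blob_sigma: float = 1.0,
    n_off_blobs: int = 0,
    off_surface_dz: float = 15.0,
    min_blob_spacing: float = 6.0,
) -> tuple[Volume, SurfaceSpec, pd.DataFrame]:
    """Cylindrically curved shell z*(x) (y-invariant) decorated with blobs.

    ``arc_params`` = {"radius", "x_center", "z_min", "x_half"} defines the
    circular arc z*(x) = z_min + R − sqrt(R² − (x − xc)²) on |x − xc| ≤ x_half.
    On-surface blobs sit at z = z*(x); ``n_off_blobs`` distractors are placed
    ``off_surface_dz`` µm above/below the surface and flagged in the table.
    """
    dz, dy, dx = voxel_size
    nz, ny, nx = shape
    lz, ly, lx = dz * (nz - 1), dy * (ny - 1), dx * (nx - 1)
    if arc_params is None:
        arc_params = {"radius": 100.0, "x_center": lx / 2, "z_min": lz * 0.25,
                      "x_half": 0.375 * lx}
    R = float(arc_params["radius"])
    xc = float(arc_params["x_center"])
    z_min = float(arc_params["z_min"])
    x_half = float(arc_params["x_half"])
    if x_half >= R:
        raise ValueError("x_half must be < radius")
    x_grid = np.arange(nx) * dx
    xa = np.clip(x_grid, xc - x_half, xc + x_half)
    z_star = z_min + R - np.sqrt(R**2 - (xa - xc) ** 2)
    if np.any(z_star < thickness) or np.any(z_star > lz - thickness):
        raise ValueError("arc exits the volume z-range")
    surface = SurfaceSpec(x_grid=x_grid, z_of_x=z_star, half_width=thickness / 2.0)

    data = np.zeros(shape, dtype=np.float32)
    zz = (np.arange(nz) * dz)[:, None]
    shell = (np.abs(zz - z_star[None, :]) < thickness / 2.0).astype(np.float32)
    data += shell_amplitude * shell[:, None, :]

    rng = np.random.default_rng(seed)
    rows = []
    placed: list[tuple[float, float]] = []

    def _place(on_surface: bool, sign: float = 1.0) -> None:
        for _ in range(2000):
            bx = rng.uniform(xc - x_half + 4 * blob_sigma, xc + x_half - 4 * blob_sigma)
            by = rng.uniform(4 * blob_sigma, ly - 4 * blob_sigma)
            if all((bx - px) ** 2 + (by - py) ** 2 > min_blob_spacing**2
                   for px, py in placed):
                break
        else:  # pragma: no cover - pathological density
            raise RuntimeError("could not place blob with requested spacing")
        zs = float(np.interp(bx, x_grid, z_star))
        bz = zs if on_surface else zs + sign * off_surface_dz
        if not 0 <= bz <= lz:
            bz = zs - off_surface_dz  # fall back below the surface
        placed.append((bx, by))
        rows.append(
            dict(x=bx, y=by, z=bz, amplitude=blob_amplitude, sigma=blob_sigma,
                 on_surface=bool(on_surface))
        )

    for _ in range(n_blobs):
        _place(True)
    for k in range(n_off_blobs):
        _place(False, sign=1.0 if k % 2 == 0 else -1.0)
    table = pd.DataFrame(rows, columns=["x", "y", "z", "amplitude", "sigma", "on_surface"])
    if len(table):
        _render_gaussian_blobs(data, voxel_size, (0.0, 0.0, 0.0), table)
    return Volume(data, voxel_size), surface, table


# ---------------------------------------------------------------------------
# calcium

def calcium_kernel(t: np.ndarray, tau_r: float = 0.05, tau_d: float = 0.5) -> np.ndarray:
    """Double-exponential transient kernel (1 − e^{−t/τ_r})·e^{−t/τ_d}, t ≥ 0.

    Defaults resemble GCaMP-family kinetics (fast rise, ~0.5 s decay).
    """
    t = np.asarray(t, dtype=float)
    k = (1.0 - np.exp(-t / tau_r)) * np.exp(-t / tau_d)
    return np.where(t >= 0, k, 0.0)


def peak_dff(amplitude: float, tau_r: float = 0.05, tau_d: float = 0.5) -> float:
    """Peak ΔF/F of a single transient: A·max_t kernel(t), by dense evaluation."""
    t = np.linspace(0.0, 10.0 * tau_d, 20001)
    return float(amplitude * calcium_kernel(t, tau_r, tau_d).max())


@dataclass(frozen=True)
class TwoLayerSpec:
    """Two axially separated layers of soma-like cells."""

    shape: tuple[int, int, int] = (48, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    layer_z: tuple[float, float] = (14.0, 34.0)
    n_cells_per_layer: int = 4
    cell_sigma: float = 2.0
    f0: float = 100.0
    amplitude: float = 0.5
    tau_r: float = 0.05
    tau_d: float = 0.5
    transients_per_cell: int = 1

    def __post_init__(self) -> None:
        if abs(self.layer_z[1] - self.layer_z[0]) <= 2 * self.cell_sigma:
            raise ValueError("layers must be separated by more than one cell diameter")


def make_calcium_phantom(
    spec: TwoLayerSpec,
    duration: float = 2.0,
    frame_interval: float = 0.05,
    seed: int | None = None,
    poisson_noise: bool = False,
    photon_scale: float = 1.0,
) -> tuple[TimeLapse, pd.DataFrame]:
    """Two-layer movie of Gaussian cells with double-exponential transients.

    Cell fluorescence follows F(t) = F0·(1 + Σ A·k(t − t_onset)); the returned
    table carries position, layer, F0, A, τ_r, τ_d and the onset times
    (';'-joined) for every cell — sufficient ground truth for dF/F recovery.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.voxel_size
    times = np.arange(0.0, duration, frame_interval)
    rows = []
    for layer, z0 in enumerate(spec.layer_z):
        for _ in range(spec.n_cells_per_layer):
            onsets = np.sort(
                rng.uniform(0.15 * duration, 0.7 * duration, spec.transients_per_cell)
            )
            rows.append(
                dict(
                    x=rng.uniform(6 * spec.cell_sigma, dx * (nx - 1) - 6 * spec.cell_sigma),
                    y=rng.uniform(6 * spec.cell_sigma, dy * (ny - 1) - 6 * spec.cell_sigma),
                    z=z0 + rng.uniform(-1.0, 1.0),
                    layer=layer,
                    sigma=spec.cell_sigma,
                    f0=spec.f0,
                    amplitude=spec.amplitude,
                    tau_r=spec.tau_r,
                    tau_d=spec.tau_d,
                    onsets=";".join(f"{t:.6f}" for t in onsets),
                )
            )
    truth = pd.DataFrame(rows)
    # warn on heavy overlap
    pos = truth[["x", "y", "z"]].to_numpy()
    if len(pos) > 1:
        d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if np.mean(d.min(1) < 2 * spec.cell_sigma) > 0.2:
            warnings.warn("more than 20% of cells overlap substantially")

    movie = np.zeros((len(times),) + spec.shape, dtype=np.float32)
    unit = np.zeros(spec.shape, dtype=np.float32)
    for i, row in truth.iterrows():
        unit[:] = 0.0
        cell_tbl = pd.DataFrame(
            [dict(x=row.x, y=row.y, z=row.z, amplitude=1.0, sigma=row.sigma)]
        )
        _render_gaussian_blobs(unit, spec.voxel_size, (0.0, 0.0, 0.0), cell_tbl)
        onsets = [float(v) for v in row.onsets.split(";")] if row.onsets else []
        f_t = np.full(len(times), row.f0)
        for t0 in onsets:
            f_t = f_t + row.f0 * row.amplitude * calcium_kernel(times - t0, row.tau_r, row.tau_d)
        movie += unit[None] * f_t[:, None, None, None].astype(np.float32)
    if poisson_noise:
        movie = rng.poisson(np.clip(movie, 0, None) * photon_scale).astype(np.float32) / photon_scale
    lapse = TimeLapse(movie, frame_interval=frame_interval, voxel_size=spec.voxel_size)
    return lapse, truth


# ---------------------------------------------------------------------------
# haze

def add_haze(
    volume: Volume,
    sigma0: float = 0.0,
    k: float = 0.0,
    pedestal_frac: float = 0.0,
    seed: int | None = None,
) -> Volume:
    """Depth-dependent scattering surrogate: blur + smooth additive pedestal.

    Each z-plane is blurred with a normalised Gaussian of width
    σ(z) = sigma0 + k·z (periodic boundaries, so the per-plane photon count
    is conserved exactly) and receives an additive pedestal equal to
    ``pedestal_frac`` × plane mean, modulated by a smooth positive random
    field of mean one.
    """
    if sigma0 < 0 or k < 0 or pedestal_frac < 0:
        raise ValueError("sigma0, k and pedestal_frac must be >= 0")
    dz, dy, dx = volume.voxel_size
    out = volume.data.astype(np.float64).copy()
    zs = volume.z_coords()
    for i, z in enumerate(zs):
        sig = sigma0 + k * z
        if sig > 0:
            out[i] = gaussian_filter(out[i], sigma=(sig / dy, sig / dx), mode="wrap")
    if pedestal_frac > 0:
        rng = np.random.default_rng(seed)
        fld = gaussian_filter(rng.uniform(0.5, 1.5, volume.data.shape[1:]),
                              sigma=8.0, mode="wrap")
        fld /= fld.mean()
        plane_means = out.reshape(out.shape[0], -1).mean(axis=1)
        out += pedestal_frac * plane_means[:, None, None] * fld[None]
    return Volume(out.astype(np.float32), volume.voxel_size, volume.origin)
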