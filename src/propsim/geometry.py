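"""Closed-form geometry of projective light-sheet imaging with parameter selection.

Coordinate conventions
----------------------
``x`` is the scan axis along the coverslip, ``y`` the sheet-invariant axis
(camera columns), and ``z`` the height above the coverslip.  All lengths are
in micrometres, times in seconds and angles in degrees.  Arrays are indexed
``(z, y, x)`` with 0-based voxel-centre coordinates.

The light sheet spans ``y`` and the in-plane unit vector
``(sin φ, 0, cos φ)``; at scan position ``s`` the sheet plane is
``{(s + t·sin φ, y, t·cos φ)}``.  A fluorophore at height ``z`` is therefore
illuminated when the scan reaches ``s_ill = x − z·tan φ`` and is imaged onto
camera row ``u = z/cos φ + g(s_ill)`` where ``g(s) = r·s + q(s) + b`` is the
total image shift produced by the shear galvo.

A rolling shutter synchronised to the shear has its active band centred at
``u_sh(s) = r·s + b + c0 + v_u·τ`` (``v_u = r·v_s`` is the shutter row speed).
The row residual

    u − u_sh = z/cos φ + q(s_ill) − c0 − v_u·τ

is independent of ``x`` and of the shear rate, which is what makes the
shutter a pure axial (z) selector: with a linear waveform (``q ≡ 0``) a
shutter of width ``W`` selects the slab

    z_depth  = W·cos φ,          z_center = (c0 + v_u·τ)·cos φ,

and a nonlinear waveform ``q(s)`` bends the selected layer into the surface
``z*(x)`` solving ``z/cos φ = c0 + v_u·τ − q(x − z·tan φ)``.

Sign conventions: positive delay ``τ`` moves the slab towards +z; positive
viewing angle ``ψ`` tilts the projection direction towards +x, with
``tan ψ = tan φ − 1/(r·cos φ)`` (``r = 1/sin φ`` gives the top-down view).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "OpticsConfig",
    "SweepConfig",
    "ShearWaveform",
    "ShutterConfig",
    "SlabSpec",
    "SurfaceSpec",
    "ViewSpec",
    "slab_bounds",
    "viewing_angle",
    "shear_rate_for_view",
    "design_shear_waveform",
    "predicted_surface",
    "local_view_angle",
    "shutter_row_speed",
    "rows_to_um",
    "um_to_rows",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge."""


@dataclass(frozen=True)
class OpticsConfig:
    """Optical geometry of the tilted-sheet microscope.

    Parameters
    ----------
    tilt_phi : float
        Tilt of the light-sheet in-plane direction from the z-axis, degrees.
        Must lie strictly between 0 and 90.
    sheet_sigma : float
        1/e half-thickness of the Gaussian sheet profile, µm.  0 means an
        ideally thin sheet.
    pixel_pitch : float
        Camera pixel size mapped to sample space, µm (magnification is fixed
        to 1: camera rows are expressed directly in sample-space µm).
    z_max : float
        Usable height above the coverslip, µm.
    """

    tilt_phi: float
    sheet_sigma: float = 0.0
    pixel_pitch: float = 1.0
    z_max: float = 128.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tilt_phi < 90.0:
            raise ValueError(f"tilt_phi must be in (0, 90) degrees, got {self.tilt_phi}")
        if self.sheet_sigma < 0:
            raise ValueError("sheet_sigma must be >= 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.z_max <= 0:
            raise ValueError("z_max must be > 0")

    @property
    def phi_rad(self) -> float:
        return math.radians(self.tilt_phi)

    @property
    def sin_phi(self) -> float:
        return math.sin(self.phi_rad)

    @property
    def cos_phi(self) -> float:
        return math.cos(self.phi_rad)

    @property
    def tan_phi(self) -> float:
        return math.tan(self.phi_rad)


@dataclass(frozen=True)
class SweepConfig:
    """Focal sweep: linear map from time to scan position s(t)."""

    s_start: float
    s_end: float
    n_steps: int
    sweep_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.s_end <= self.s_start:
            raise ValueError("s_end must be > s_start")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.sweep_duration <= 0:
            raise ValueError("sweep_duration must be > 0")

    @property
    def span(self) -> float:
        return self.s_end - self.s_start

    @property
    def v_s(self) -> float:
        """Scan speed, µm/s."""
        return self.span / self.sweep_duration

    @property
    def delta_s(self) -> float:
        return self.span / (self.n_steps - 1)

    def s_grid(self) -> np.ndarray:
        return np.linspace(self.s_start, self.s_end, self.n_steps)


@dataclass(frozen=True)
class ShearWaveform:
    """Image shift g(s) = rate_r·s + q(s) + offset_b applied during the sweep.

    ``nonlinear_q`` is a sampled function q(s): a pair of arrays
    ``(s_samples, q_samples)`` on a strictly increasing grid; ``None`` means
    q ≡ 0 (a linear waveform).  Outside the sampled grid q is held constant
    at its end values.
    """

    rate_r: float
    offset_b: float = 0.0
    nonlinear_q: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.rate_r <= 0:
            raise ValueError("rate_r must be > 0")
        if self.nonlinear_q is not None:
            s, q = (np.asarray(a, dtype=float) for a in self.nonlinear_q)
            if s.ndim != 1 or s.shape != q.shape or s.size < 2:
                raise ValueError("nonlinear_q must be two equal-length 1-D arrays")
            if not np.all(np.diff(s) > 0):
                raise ValueError("nonlinear_q s-grid must be strictly increasing")
            if not (np.all(np.isfinite(s)) and np.all(np.isfinite(q))):
                raise ValueError("nonlinear_q must be finite")
            object.__setattr__(self, "nonlinear_q", (s, q))

    @property
    def is_linear(self) -> bool:
        return self.nonlinear_q is None or bool(np.all(self.nonlinear_q[1] == 0.0))

    def q(self, s: np.ndarray | float) -> np.ndarray | float:
        if self.nonlinear_q is None:
            return np.zeros_like(np.asarray(s, dtype=float)) if np.ndim(s) else 0.0
        sg, qg = self.nonlinear_q
        return np.interp(s, sg, qg)

    def g(self, s: np.ndarray | float) -> np.ndarray | float:
        return self.rate_r * np.asarray(s, dtype=float) + self.q(s) + self.offset_b


@dataclass(frozen=True)
class ShutterConfig:
    """Rolling-shutter window in sample-space row units (µm)."""

    width_W: float
    center_c0: float = 0.0
    delay_tau: float = 0.0
    synchronized: bool = True

    def __post_init__(self) -> None:
        if self.width_W < 0:
            raise ValueError("width_W must be >= 0")


@dataclass(frozen=True)
class SlabSpec:
    """Flat axial sub-volume selected by the shutter: centre and depth in µm."""

    z_center: float
    z_depth: float
    weighting: str = "hard"

    def __post_init__(self) -> None:
        if self.z_depth < 0:
            raise ValueError("z_depth must be >= 0")
        if self.weighting not in ("hard", "gaussian"):
            raise ValueError("weighting must be 'hard' or 'gaussian'")

    @property
    def z_lo(self) -> float:
        return self.z_center - self.z_depth / 2.0

    @property
    def z_hi(self) -> float:
        return self.z_center + self.z_depth / 2.0


@dataclass(frozen=True)
class SurfaceSpec:
    """Curved target layer z*(x), sampled on a strictly increasing x-grid."""

    x_grid: np.ndarray
    z_of_x: np.ndarray
    half_width: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x_grid, dtype=float)
        z = np.asarray(self.z_of_x, dtype=float)
        if x.ndim != 1 or x.shape != z.shape or x.size < 2:
            raise ValueError("x_grid and z_of_x must be equal-length 1-D arrays")
        if not np.all(np.diff(x) > 0):
            raise ValueError("x_grid must be strictly increasing")
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        object.__setattr__(self, "x_grid", x)
        object.__setattr__(self, "z_of_x", z)

    def z(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.interp(x, self.x_grid, self.z_of_x)

    def max_slope(self) -> float:
        return float(np.max(np.abs(np.gradient(self.z_of_x, self.x_grid))))


@dataclass(frozen=True)
class ViewSpec:
    """Signed viewing angle ψ (degrees) from the z-axis in the x–z plane."""

    psi: float

    def __post_init__(self) -> None:
        if not abs(self.psi) < 90.0:
            raise ValueError("|psi| must be < 90 degrees")

    @property
    def tan_psi(self) -> float:
        return math.tan(math.radians(self.psi))


def rows_to_um(rows: float, optics: OpticsConfig) -> float:
    """Convert a camera row count to sample-space µm."""
    return rows * optics.pixel_pitch


def um_to_rows(um: float, optics: OpticsConfig) -> float:
    """Convert sample-space µm to camera rows."""
    return um / optics.pixel_pitch


def shutter_row_speed(shear: ShearWaveform, sweep: SweepConfig) -> float:
    """Row speed v_u = r·v_s of the synchronised shutter band, µm/s."""
    return shear.rate_r * sweep.v_s


def slab_bounds(
    shutter: ShutterConfig,
    optics: OpticsConfig,
    sweep: SweepConfig,
    shear: ShearWaveform,
) -> SlabSpec:
    """Slab selected by a synchronised shutter with a linear shear waveform.

    The row residual u − u_sh = z/cos φ − c0 − v_u·τ depends only on z, so
    the shutter window of width W selects z_depth = W·cos φ centred at
    z_center = (c0 + v_u·τ)·cos φ.  The slab is clipped to [0, z_max] with a
    warning if it extends outside.
    """
    if not shutter.synchronized:
        raise ValueError("slab_bounds requires a synchronized shutter")
    if not shear.is_linear:
        raise ValueError(
            "slab_bounds requires a linear waveform (q ≡ 0); "
            "use predicted_surface for nonlinear waveforms"
        )
    v_u = shutter_row_speed(shear, sweep)
    z_c = (shutter.center_c0 + v_u * shutter.delay_tau) * optics.cos_phi
    dz = shutter.width_W * optics.cos_phi
    lo, hi = z_c - dz / 2.0, z_c + dz / 2.0
    clo, chi = max(lo, 0.0), min(hi, optics.z_max)
    if chi < clo:
        warnings.warn("selected slab lies entirely outside [0, z_max]; empty slab")
        return SlabSpec(z_center=min(max(z_c, 0.0), optics.z_max), z_depth=0.0)
    if clo > lo or chi < hi:
        warnings.warn(
            f"slab [{lo:.3g}, {hi:.3g}] µm partially outside [0, {optics.z_max:g}]; clipped"
        )
    return SlabSpec(z_center=(clo + chi) / 2.0, z_depth=chi - clo)


def viewing_angle(shear: ShearWaveform, optics: OpticsConfig) -> ViewSpec:
    """Viewing angle realised by shear rate r: tan ψ = tan φ − 1/(r·cos φ).

    Camera rows collect signal along the sample lines x = x0 + z·tan ψ;
    r = 1/sin φ gives ψ = 0 (top-down projection).
    """
    if not shear.is_linear:
        raise ValueError("viewing_angle is defined for linear waveforms; "
                         "see local_view_angle for the nonlinear diagnostic")
    tan_psi = optics.tan_phi - 1.0 / (shear.rate_r * optics.cos_phi)
    return ViewSpec(psi=math.degrees(math.atan(tan_psi)))


def shear_rate_for_view(psi: float | ViewSpec, optics: OpticsConfig) -> float:
    """Inverse of :func:`viewing_angle`: r = 1/(cos φ·(tan φ − tan ψ)).

    Angles ψ ≥ φ are unreachable (they would need r ≤ 0 or ∞).
    """
    psi_deg = psi.psi if isinstance(psi, ViewSpec) else float(psi)
    if psi_deg >= optics.tilt_phi:
        raise ValueError(
            f"viewing angle {psi_deg}° is unreachable for tilt {optics.tilt_phi}° "
            "(requires r <= 0 or infinite)"
        )
    denom = optics.cos_phi * (optics.tan_phi - math.tan(math.radians(psi_deg)))
    return 1.0 / denom


def design_shear_waveform(
    surface: SurfaceSpec,
    optics: OpticsConfig,
    shutter: ShutterConfig,
    shear_base: ShearWaveform,
    sweep: SweepConfig,
) -> ShearWaveform:
    """Nonlinear waveform q(s) that bends the selected layer onto z*(x).

    For each x the surface point (x, z*(x)) is illuminated at
    s(x) = x − z*(x)·tan φ; inverting this (monotone PCHIP interpolation)
    gives x(s), and q(s) = c0 + v_u·τ − z*(x(s))/cos φ zeroes the shutter
    residual exactly on the surface.  Requires the invertibility bound
    max|dz*/dx|·tan φ < 1 and the surface's scan range inside the sweep.
    """
    x = surface.x_grid
    z = surface.z_of_x
    if np.any(z < 0) or np.any(z > optics.z_max):
        raise ValueError("surface must lie within [0, z_max]")
    s_of_x = x - z * optics.tan_phi
    ds = np.diff(s_of_x)
    if np.any(ds <= 0):
        i = int(np.argmax(ds <= 0))
        raise ValueError(
            "surface is not invertible at this tilt: s(x) is non-increasing on "
            f"x ∈ [{x[i]:.3g}, {x[i + 1]:.3g}] µm (need max|dz*/dx|·tan φ < 1)"
        )
    if s_of_x[0] < sweep.s_start - 1e-9 or s_of_x[-1] > sweep.s_end + 1e-9:
        raise ValueError(
            f"surface scan range [{s_of_x[0]:.3g}, {s_of_x[-1]:.3g}] µm extends "
            f"beyond the sweep [{sweep.s_start:g}, {sweep.s_end:g}] µm"
        )
    x_of_s = PchipInterpolator(s_of_x, x, extrapolate=False)
    s_grid = sweep.s_grid()
    xs = x_of_s(np.clip(s_grid, s_of_x[0], s_of_x[-1]))
    z_star = surface.z(xs)
    v_u = shutter_row_speed(shear_base, sweep)
    q = shutter.center_c0 + v_u * shutter.delay_tau - z_star / optics.cos_phi
    return replace(shear_base, nonlinear_q=(s_grid, np.asarray(q)))


def predicted_surface(
    shear: ShearWaveform,
    optics: OpticsConfig,
    shutter: ShutterConfig,
    sweep: SweepConfig,
    x_grid: np.ndarray,
    tol: float = 0.01,
    max_iter: int = 50,
) -> SurfaceSpec:
    """Layer z_c(x) selected by an arbitrary waveform (inverse of the design).

    Solves z_c(x)/cos φ = c0 + v_u·τ − q(x − z_c(x)·tan φ) by damped
    fixed-point iteration starting from z_c = cos φ·(c0 + v_u·τ − q(x)).
    The plain iteration map g(z) = cos φ·(c − q(x − z·tan φ)) has derivative
    g' = cos φ·tan φ·dq/ds, which equals −β/(1−β) for a designed waveform
    with surface slope β = (dz*/dx)·tan φ; it contracts unaided only for
    β < 1/2.  Since g' < 1 throughout the invertible regime, the iteration
    is damped with the optimal relaxation α = 2/(2 − lo − hi) computed from
    the waveform's own slope bounds [lo, hi] of g' (α = 1, the plain
    iteration, when q ≡ 0).  Returns the surface with
    half_width = W·cos φ / 2.
    """
    x = np.asarray(x_grid, dtype=float)
    v_u = shutter_row_speed(shear, sweep)
    c = shutter.center_c0 + v_u * shutter.delay_tau

    def g(z: np.ndarray) -> np.ndarray:
        return optics.cos_phi * (c - np.asarray(shear.q(x - z * optics.tan_phi)))

    if shear.nonlinear_q is None:
        lo = hi = 0.0
    else:
        sg, qg = shear.nonlinear_q
        gp = optics.cos_phi * optics.tan_phi * np.gradient(qg, sg)
        lo, hi = min(float(gp.min()), 0.0), max(float(gp.max()), 0.0)
    if hi >= 1.0:
        raise ConvergenceError(
            f"waveform slope makes the selected layer non-invertible (g' reaches {hi:.3g})"
        )
    alpha = 2.0 / (2.0 - lo - hi)
    z_c = optics.cos_phi * (c - np.asarray(shear.q(x)))
    converged = False
    for _ in range(max_iter):
        z_new = z_c + alpha * (g(z_c) - z_c)
        delta = float(np.max(np.abs(z_new - z_c)))
        z_c = z_new
        if delta < tol * alpha:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"predicted_surface did not converge below {tol} µm in {max_iter} iterations"
        )
    return SurfaceSpec(
        x_grid=x, z_of_x=z_c, half_width=shutter.width_W * optics.cos_phi / 2.0
    )


def local_view_angle(
    shear: ShearWaveform, optics: OpticsConfig, s: np.ndarray | float
) -> np.ndarray | float:
    """Diagnostic: viewing angle (degrees) at scan position s for a nonlinear
    waveform, using the effective local shear rate r + dq/ds."""
    if shear.nonlinear_q is None:
        dq = np.zeros_like(np.asarray(s, dtype=float))
    else:
        sg, qg = shear.nonlinear_q
        dq = np.interp(s, sg, np.gradient(qg, sg))
    r_eff = shear.rate_r + dq
    tan_psi = optics.tan_phi - 1.0 / (r_eff * optics.cos_phi)
    return np.degrees(np.arctan(tan_psi))
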