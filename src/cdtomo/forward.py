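"""Forward measurement model for confocal scanning through a diffusive slab.

A pulsed source and time-resolved detector share an optical path and
raster-scan a grid of points on the slab's near face (z = 0). Light diffuses
through the slab, propagates in free space to the hidden scene (z >= z_d),
returns, and diffuses back out. The exact model composes two one-way
diffusion responses with the one-bounce free-space transient; the confocal
approximation collapses this to a spatio-temporal convolution of the
two-way diffusion kernel phi_bar with the confocal free-space transient.

All free-space path lengths are measured from the slab's far face
(z = z_d); lateral coordinates come from the scan grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import irfft, rfft
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .diffusion import DiffusionKernel, sampled_kernel, transmittance_phi, two_way_kernel
from .slab import C0, OpticalSlab, default_dipoles

REFLECTANCE_MODELS = ("isotropic", "lambertian", "retroreflective")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ScanGrid:
    """Confocal scan raster on the slab's near face (z = 0), centered on axis."""

    nx: int
    ny: int
    pitch: float

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx, ny must be >= 1")
        if not self.pitch > 0:
            raise ValueError("pitch must be positive")

    @property
    def half_width(self) -> float:
        """Aperture half-extent w = pitch (nx - 1) / 2, cm."""
        return self.pitch * (self.nx - 1) / 2.0

    @property
    def xs(self) -> np.ndarray:
        return (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.pitch

    @property
    def ys(self) -> np.ndarray:
        return (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.pitch

    def positions(self) -> np.ndarray:
        """(nx*ny, 2) lateral scan positions in row-major (x-major) order."""
        gx, gy = np.meshgrid(self.xs, self.ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


def prototype_grid(nx: int = 32, ny: int = 32, aperture: float = 70.0) -> ScanGrid:
    """The prototype raster: 32 x 32 points over a 70 cm square aperture."""
    return ScanGrid(nx=nx, ny=ny, pitch=aperture / (nx - 1))


@dataclass(frozen=True)
class HiddenScene:
    """Voxelized hidden-object albedo in the half-space beyond the slab.

    ``albedo[i, j, k]`` is the albedo of the voxel centered at
    origin + (i, j, k) * voxel_size; all voxels must sit at z >= the exit
    plane used by the simulator. ``reflectance_model`` selects the
    one-bounce throughput f(x, r):

    - ``isotropic``: f = 1/r^2, confocal falloff 1/r^4
    - ``lambertian``: f = cos(theta)/r^2 with the voxel normal facing the
      slab (-z), confocal falloff cos^2/r^4
    - ``retroreflective``: f = 1/r, confocal falloff 1/r^2
    """

    albedo: np.ndarray
    origin: tuple[float, float, float]
    voxel_size: tuple[float, float, float]
    reflectance_model: str = "isotropic"

    def __post_init__(self) -> None:
        a = np.asarray(self.albedo)
        if a.ndim != 3:
            raise ValueError("albedo must be a 3D array")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("albedo must be finite and non-negative")
        if self.reflectance_model not in REFLECTANCE_MODELS:
            raise ValueError(
                f"unknown reflectance model {self.reflectance_model!r}; "
                f"choose from {REFLECTANCE_MODELS}")

    def point_cloud(self) -> tuple[np.ndarray, np.ndarray]:
        """Nonzero voxels as (positions (N, 3), weights (N,))."""
        idx = np.argwhere(self.albedo > 0)
        if idx.size == 0:
            return np.zeros((0, 3)), np.zeros(0)
        pos = np.asarray(self.origin) + idx * np.asarray(self.voxel_size)
        return pos, self.albedo[idx[:, 0], idx[:, 1], idx[:, 2]]


def point_scene(x: float, y: float, z: float, *, albedo: float = 1.0,
                reflectance_model: str = "isotropic",
                voxel_size: float = 1.0) -> HiddenScene:
    """Single-voxel scene at an absolute position (z measured from z = 0)."""
    a = np.full((1, 1, 1), float(albedo))
    return HiddenScene(albedo=a, origin=(x, y, z),
                       voxel_size=(voxel_size,) * 3,
                       reflectance_model=reflectance_model)


@dataclass(frozen=True)
class InstrumentResponse:
    """Timing response and photon budget of the source/detector chain.

    ``irf_fwhm`` lumps the laser pulse width and detector jitter into one
    Gaussian (prototype: ~35 ps pulse + SPAD jitter -> ~70 ps combined).
    """

    irf_fwhm: float = 0.070
    gate_start: float = 0.0
    mean_signal_photons: float = 1e4
    dark_rate: float = 0.0
    pulse_rep_rate: float = 10e6

    def __post_init__(self) -> None:
        if self.irf_fwhm < 0 or self.gate_start < 0:
            raise ValueError("irf_fwhm and gate_start must be >= 0")
        if self.mean_signal_photons < 0 or self.dark_rate < 0:
            raise ValueError("photon rates must be >= 0")


@dataclass(frozen=True)
class MeasurementVolume:
    """Confocal scan-grid x time-bin volume (expected flux or photon counts).

    ``data[ix, iy, it]`` is the signal at scan point (ix, iy) in the time
    sample it * dt (round-trip time measured from the pulse leaving the
    near face; samples at t = k dt).
    """

    data: np.ndarray
    dt: float
    grid: ScanGrid
    gate_start: float = 0.0
    is_counts: bool = False
    meta: dict | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3 or d.shape[:2] != (self.grid.nx, self.grid.ny):
            raise ValueError("data must be (nx, ny, nt) matching the grid")
        if np.any(d < 0):
            raise ValueError("measurement data must be non-negative")
        if self.is_counts and not np.issubdtype(d.dtype, np.integer):
            raise ValueError("count volumes must have integer dtype")

    @property
    def nt(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.nt) * self.dt


def _throughput(dist: np.ndarray, axial: np.ndarray, model: str) -> np.ndarray:
    """One-way free-space throughput f(x, r) for each reflectance model."""
    if model == "isotropic":
        return 1.0 / dist**2
    if model == "lambertian":
        return axial / dist**3  # cos(theta)/r^2 with normal along -z
    if model == "retroreflective":
        return 1.0 / dist
    raise ValueError(f"unknown reflectance model {model!r}")


def _bin_deposit(out: np.ndarray, rows: np.ndarray, t_arrival: np.ndarray,
                 weights: np.ndarray, dt: float, nt: int) -> None:
    """Energy-preserving linear split of each arrival onto the two nearest bins."""
    idx = t_arrival / dt
    i0 = np.floor(idx).astype(int)
    w1 = idx - i0
    np.add.at(out, (rows, i0), weights * (1.0 - w1))
    np.add.at(out, (rows, np.minimum(i0 + 1, nt - 1)), weights * w1)


def freespace_transient_confocal(
    scene: HiddenScene,
    grid: ScanGrid,
    dt: float,
    nt: int,
    *,
    exit_plane_z: float = 0.0,
) -> MeasurementVolume:
    """Noiseless, diffusion-free confocal transient I(t, r, r).

    For each scan point r the one-bounce return from voxel x arrives at
    t = 2 ||x - r'|| / c0, where r' is the scan point projected onto the
    exit plane z = ``exit_plane_z``, with amplitude albedo * f(x, r')^2.
    Arrivals later than the histogram window (possible for far off-axis
    scan points) are simply not recorded, as in a real acquisition; a
    voxel whose on-axis return already falls outside the window raises.
    """
    if dt <= 0 or nt < 1:
        raise ValueError("dt must be positive and nt >= 1")
    pos, weights = scene.point_cloud()
    out = np.zeros((grid.nx * grid.ny, nt))
    if len(pos):
        if np.any(pos[:, 2] < exit_plane_z):
            bad = pos[pos[:, 2] < exit_plane_z][0]
            raise ValueError(f"voxel at {tuple(bad)} lies before the exit plane "
                             f"z = {exit_plane_z}")
        axial = pos[:, 2] - exit_plane_z
        t_axial = 2.0 * axial / C0
        if np.any(t_axial >= (nt - 1) * dt):
            bad = pos[np.argmax(t_axial)]
            raise ValueError(
                f"voxel at {tuple(bad)} is axially beyond the temporal range: "
                f"nearest return {t_axial.max():.3f} ns >= {(nt - 1) * dt:.3f} ns")
        scan = grid.positions()  # (ns, 2)
        dxy2 = ((scan[:, None, :] - pos[None, :, :2]) ** 2).sum(axis=-1)
        dist = np.sqrt(dxy2 + axial**2)  # (ns, nv)
        t_arr = 2.0 * dist / C0
        g = weights * _throughput(dist, axial, scene.reflectance_model) ** 2
        rows = np.broadcast_to(np.arange(out.shape[0])[:, None], dist.shape)
        keep = (t_arr < (nt - 1) * dt).ravel()
        _bin_deposit(out, rows.ravel()[keep], t_arr.ravel()[keep],
                     g.ravel()[keep], dt, nt)
    data = out.reshape(grid.nx, grid.ny, nt)
    return MeasurementVolume(data=data, dt=dt, grid=grid,
                             meta={"exit_plane_z": exit_plane_z})


def freespace_transient_full(
    scene: HiddenScene,
    r1: tuple[float, float],
    r2: tuple[float, float],
    dt: float,
    nt: int,
    *,
    exit_plane_z: float = 0.0,
) -> np.ndarray:
    """One-bounce transient I(t, r1, r2) between two exit-plane points.

    ``r1`` and ``r2`` are lateral coordinates on the plane z =
    ``exit_plane_z``; each voxel contributes
    albedo * f(x, r1) f(x, r2) at t = (||x - r1|| + ||x - r2||)/c0.
    """
    pos, weights = scene.point_cloud()
    out = np.zeros((1, nt))
    if len(pos) == 0:
        return out[0]
    axial = pos[:, 2] - exit_plane_z
    if np.any(axial < 0):
        raise ValueError("scene voxels must lie beyond the exit plane")
    d1 = np.sqrt(((pos[:, :2] - np.asarray(r1)) ** 2).sum(axis=1) + axial**2)
    d2 = np.sqrt(((pos[:, :2] - np.asarray(r2)) ** 2).sum(axis=1) + axial**2)
    t_arr = (d1 + d2) / C0
    if np.any(2.0 * axial / C0 >= (nt - 1) * dt):
        k = int(np.argmax(axial))
        raise ValueError(f"voxel at {tuple(pos[k])} axially beyond temporal range")
    f1 = _throughput(d1, axial, scene.reflectance_model)
    f2 = _throughput(d2, axial, scene.reflectance_model)
    keep = t_arr < (nt - 1) * dt
    _bin_deposit(out, np.zeros(int(keep.sum()), dtype=int), t_arr[keep],
                 (weights * f1 * f2)[keep], dt, nt)
    return out[0]


def convolve_kernel(data: np.ndarray, kernel: DiffusionKernel) -> np.ndarray:
    """Linear spatio-temporal convolution of a scan volume with a kernel.

    The kernel's lateral axes are centered on zero offset (index nx//2) and
    its time axis starts at zero lag; the output is cropped back to the
    input grid.
    """
    k = kernel.values
    full = fftconvolve(data, k, mode="full")
    cx, cy = k.shape[0] // 2, k.shape[1] // 2
    return full[cx:cx + data.shape[0], cy:cy + data.shape[1], :data.shape[2]]


def apply_irf(data: np.ndarray, irf_fwhm: float, dt: float) -> np.ndarray:
    """Temporal Gaussian blur of the stated FWHM (zero group delay)."""
    if irf_fwhm <= 0:
        return data
    sigma_bins = irf_fwhm * _FWHM_TO_SIGMA / dt
    return gaussian_filter1d(data, sigma_bins, axis=-1, mode="constant")


def simulate_confocal(
    scene: HiddenScene,
    slab: OpticalSlab,
    grid: ScanGrid,
    irf: InstrumentResponse,
    dt: float,
    nt: int,
    *,
    max_order: int = 3,
    kernel: DiffusionKernel | None = None,
) -> MeasurementVolume:
    """Confocal measurement model: tau_hat = phi_bar * I, blurred and gated.

    Builds the two-way diffusion kernel on the scan grid (unless a
    pre-built ``kernel`` is supplied), convolves it with the confocal
    free-space transient, applies the Gaussian instrument response, then
    the detector gate.
    """
    if kernel is None:
        one_way = sampled_kernel(slab, grid.pitch, grid.pitch, dt,
                                 grid.nx, grid.ny, nt, max_order=max_order)
        kernel = two_way_kernel(one_way)
    else:
        if not (np.isclose(kernel.dx, grid.pitch) and np.isclose(kernel.dy, grid.pitch)):
            raise ValueError("kernel pitch does not match scan pitch")
        if not np.isclose(kernel.dt, dt):
            raise ValueError("kernel dt does not match measurement dt")
    free = freespace_transient_confocal(scene, grid, dt, nt, exit_plane_z=slab.z_d)
    data = convolve_kernel(free.data, kernel)
    data = apply_irf(data, irf.irf_fwhm, dt)
    data = np.maximum(data, 0.0)
    m = MeasurementVolume(data=data, dt=dt, grid=grid,
                          meta={"slab": slab, "irf_fwhm": irf.irf_fwhm})
    if irf.gate_start > 0:
        m = apply_gating(m, irf.gate_start)
    return m


def simulate_full(
    scene: HiddenScene,
    slab: OpticalSlab,
    grid: ScanGrid,
    exit_plane_resolution: float,
    dt: float,
    nt: int,
    *,
    spot_width: float = 2.2,
    max_order: int = 3,
    max_terms: int = 10**9,
) -> MeasurementVolume:
    """Brute-force measurement model without the confocal approximation.

    For each scan point r0 the exit plane is sampled on a square patch of
    side 3 x ``spot_width`` centered at r0, and the contribution of every
    pair (r1, r2) of exit samples is accumulated:

        tau(t, r0) = sum_{r1, r2} phi(., r0, r1) * I(., r1, r2) * phi(., r0, r2)

    computed in the temporal frequency domain, where the pairwise double
    sum factorizes as the square of a single sum over r1 for each voxel.
    Each exit sample carries an area weight (resolution / pitch)^2 so that
    amplitudes are directly comparable to :func:`simulate_confocal` (whose
    implicit exit sampling is the scan pitch itself). Intended for small
    validation instances only: cost is O(n_scan * n_exit * n_voxel * nt).
    """
    if exit_plane_resolution <= 0:
        raise ValueError("exit_plane_resolution must be positive")
    pos, weights = scene.point_cloud()
    half = 1.5 * spot_width
    n_side = max(int(np.floor(2 * half / exit_plane_resolution)) + 1, 1)
    n_exit = n_side**2
    n_terms = grid.nx * grid.ny * n_exit * n_exit * max(len(pos), 1)
    if n_terms > max_terms:
        raise ValueError(
            f"instance too large ({n_terms:.2e} pairwise terms); shrink the scan "
            "grid, the scene, or increase exit_plane_resolution")

    offs = (np.arange(n_side) - (n_side - 1) / 2.0) * exit_plane_resolution
    ex, ey = np.meshgrid(offs, offs, indexing="ij")
    exit_off = np.column_stack([ex.ravel(), ey.ravel()])  # (ne, 2)
    area_w = (exit_plane_resolution / grid.pitch) ** 2

    dipoles = default_dipoles(slab, max_order=max_order)
    t = np.arange(nt) * dt
    # one-way diffusion transient for each exit offset (shared across scan points)
    rho = np.hypot(exit_off[:, 0], exit_off[:, 1])
    phi_t = np.stack([transmittance_phi(t, (r, 0.0), slab, dipoles) for r in rho])

    scan = grid.positions()
    out = np.zeros((grid.nx * grid.ny, nt))
    if len(pos) == 0:
        data = out.reshape(grid.nx, grid.ny, nt)
        return MeasurementVolume(data=data, dt=dt, grid=grid,
                                 meta={"slab": slab,
                                       "exit_plane_resolution": exit_plane_resolution})
    axial = pos[:, 2] - slab.z_d
    if np.any(axial < 0):
        raise ValueError("scene voxels must lie beyond the slab's far face")
    if np.any(2.0 * axial / C0 >= (nt - 1) * dt):
        raise ValueError("voxel axially beyond the temporal range for this grid")
    # FFT length long enough that no pairwise arrival wraps around
    corner = np.linalg.norm([grid.half_width + half, grid.half_width + half,
                             float(axial.max())])
    nfft = max(2 * nt, int(np.ceil(2 * corner / C0 / dt)) + nt + 2)
    phi_f = rfft(phi_t, n=nfft, axis=1)  # (ne, nf)
    for s, r0 in enumerate(scan):
        r1 = r0 + exit_off  # (ne, 2)
        dxy2 = ((r1[:, None, :] - pos[None, :, :2]) ** 2).sum(axis=-1)
        dist = np.sqrt(dxy2 + axial[None, :] ** 2)  # (ne, nv)
        t_arr = dist / C0
        f = _throughput(dist, axial[None, :], scene.reflectance_model)
        # binned one-way delay impulses, matching the confocal model's
        # linear time-bin deposit
        imp = np.zeros((dist.size, nfft))
        _bin_deposit(imp, np.arange(dist.size), t_arr.ravel(),
                     np.ones(dist.size), dt, nfft)
        delay_f = rfft(imp, axis=1).reshape(dist.shape + (-1,))  # (ne, nv, nf)
        bracket = (phi_f[:, None, :] * f[..., None] * delay_f).sum(axis=0)
        tau_f = (weights[:, None] * bracket**2).sum(axis=0) * area_w**2
        out[s] = irfft(tau_f, n=nfft)[:nt]
    data = np.maximum(out.reshape(grid.nx, grid.ny, nt), 0.0)
    return MeasurementVolume(data=data, dt=dt, grid=grid,
                             meta={"slab": slab, "exit_plane_resolution": exit_plane_resolution})


def apply_gating(m: MeasurementVolume, gate_start: float) -> MeasurementVolume:
    """Zero every time sample earlier than ``gate_start`` (detector gate)."""
    if gate_start < 0 or gate_start >= m.nt * m.dt:
        raise ValueError(f"gate_start {gate_start} outside [0, {m.nt * m.dt:.3f}) ns")
    if gate_start == 0:
        return m
    data = m.data.copy()
    mask = m.times < gate_start
    data[:, :, mask] = 0
    if mask.all():
        warnings.warn("gate_start falls after the last time bin; volume is all zero",
                      stacklevel=2)
    return replace(m, data=data, gate_start=gate_start)


def add_poisson_noise(
    m: MeasurementVolume,
    mean_signal_photons: float,
    dark_rate: float,
    seed: int,
) -> MeasurementVolume:
    """Draw photon counts from the expected-flux volume.

    The volume is rescaled so the mean total signal per scan point equals
    ``mean_signal_photons``; ``dark_rate`` (counts / ns / scan point) adds a
    uniform background of dark_rate * dt per bin. Deterministic for a
    fixed seed.
    """
    if mean_signal_photons < 0 or dark_rate < 0:
        raise ValueError("photon rates must be non-negative")
    per_point = m.data.sum(axis=2).mean()
    if mean_signal_photons > 0 and per_point <= 0:
        raise ValueError("cannot scale an all-zero volume to a positive photon budget")
    scale = mean_signal_photons / per_point if mean_signal_photons > 0 else 0.0
    lam = m.data * scale + dark_rate * m.dt
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    return replace(m, data=counts, is_counts=True,
                   meta={**(m.meta or {}), "noise_scale": scale, "seed": seed})
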