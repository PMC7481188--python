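"""Inverse methods: Wiener deconvolution of the diffusion kernel followed by
a confocal inverse filter (f-k migration or the Light-Cone Transform).

The measurement model factorizes as tau = phi_bar * A rho, where phi_bar is
the two-way diffusion kernel and A is confocal one-bounce free-space
propagation. The closed-form inverse applies the 3D Wiener filter

    F^-1 [ conj(Phi_hat) / (|Phi_hat|^2 + 1/alpha) ] F tau

to undo the diffusive blur (including the bulk time delay through the
slab, which lives in the kernel's phase), then inverts A with a standard
confocal reconstruction operator. Cost is dominated by 3D FFTs.
"""

from __future__ import annotations


from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import fftfreq, fftn, fftshift, ifftn, ifftshift
from scipy.signal import fftconvolve

from .diffusion import DiffusionKernel, sampled_kernel, two_way_kernel
from .forward import MeasurementVolume
from .slab import C0, OpticalSlab


@dataclass(frozen=True)
class WienerConfig:
    """Wiener deconvolution settings.

    alpha is the signal-to-noise parameter: the filter denominator is
    |Phi_hat|^2 + 1/alpha_eff. With ``relative=True`` (default),
    1/alpha_eff = max|Phi_hat|^2 / alpha, so alpha = 10 damps frequencies
    whose kernel power falls below a tenth of the peak, independent of
    kernel scale. alpha may also be a per-frequency array broadcastable to
    the padded spectrum.
    """

    alpha: float | np.ndarray = 10.0
    relative: bool = True
    pad_factor: int = 2

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.alpha) <= 0):
            raise ValueError("alpha must be positive")
        if self.pad_factor not in (1, 2):
            raise ValueError("pad_factor must be 1 or 2")


@dataclass(frozen=True)
class ReconstructionVolume:
    """Recovered albedo on an (x, y, z) grid.

    Depth maps from round-trip free-space time: slice k sits at
    z = z0 + k * dz with dz = c dt / 2 and z0 the slab's far face.
    """

    albedo: np.ndarray
    voxel_size: tuple[float, float, float]
    z0: float = 0.0
    meta: dict | None = None

    @property
    def zs(self) -> np.ndarray:
        return self.z0 + np.arange(self.albedo.shape[2]) * self.voxel_size[2]

    def argmax_position(self) -> tuple[float, float, float]:
        """Physical (x, y, z) of the brightest voxel (x, y centered on axis)."""
        i, j, k = np.unravel_index(np.argmax(self.albedo), self.albedo.shape)
        nx, ny, _ = self.albedo.shape
        x = (i - (nx - 1) / 2.0) * self.voxel_size[0]
        y = (j - (ny - 1) / 2.0) * self.voxel_size[1]
        return x, y, self.z0 + k * self.voxel_size[2]


def _wiener_apply(data: np.ndarray, kernel_vals: np.ndarray,
                  kernel_center: tuple[int, int],
                  cfg: WienerConfig) -> np.ndarray:
    """Shared 3D Wiener deconvolution on a zero-padded grid."""
    nx, ny, nt = data.shape
    p = cfg.pad_factor
    shape = (p * nx, p * ny, p * nt)
    kpad = np.zeros(shape)
    kx, ky, kt = kernel_vals.shape
    kpad[:kx, :ky, :kt] = kernel_vals
    # move the kernel's zero lateral offset to the array origin
    kpad = np.roll(kpad, (-kernel_center[0], -kernel_center[1]), axis=(0, 1))
    spec = fftn(kpad)
    power = np.abs(spec) ** 2
    peak = power.max()
    if peak == 0:
        raise ValueError("kernel is identically zero")
    inv_alpha = (peak / cfg.alpha) if cfg.relative else (1.0 / cfg.alpha)
    filt = np.conj(spec) / (power + inv_alpha)
    out = ifftn(fftn(data, s=shape) * filt).real
    return out[:nx, :ny, :nt]


def wiener_deconvolve(
    m: MeasurementVolume,
    kernel: DiffusionKernel,
    cfg: WienerConfig | None = None,
) -> MeasurementVolume:
    """Deconvolve the two-way diffusion kernel from a measurement volume.

    Returns a diffusion-compensated volume estimating the free-space
    confocal transient I. The kernel's onset delay is part of its spectrum,
    so deconvolution also removes the bulk time delay induced by the
    scattering layer. Linear in the measurement; padded FFTs give
    linear-convolution semantics.
    """
    cfg = cfg or WienerConfig()
    kx, ky, _ = kernel.values.shape
    if kx > 1 and not np.isclose(kernel.dx, m.grid.pitch):
        raise ValueError("kernel pitch must match the measurement grid pitch")
    if kx > m.data.shape[0] or ky > m.data.shape[1]:
        raise ValueError("kernel lateral support exceeds the measurement grid")
    data = np.asarray(m.data, dtype=float)
    center = (kernel.values.shape[0] // 2, kernel.values.shape[1] // 2)
    out = _wiener_apply(data, kernel.values, center, cfg)
    return replace(m, data=np.maximum(out, 0.0), is_counts=False,
                   meta={**(m.meta or {}), "wiener_alpha": np.asarray(cfg.alpha).tolist(),
                         "wiener_relative": cfg.relative})


def _stolt_interp(tvol: np.ndarray, f_axis: np.ndarray, f_target: np.ndarray) -> np.ndarray:
    """Linear interpolation of the fftshifted spectrum along the f axis."""
    f0, df = f_axis[0], f_axis[1] - f_axis[0]
    idx = (f_target - f0) / df
    i0 = np.floor(idx).astype(int)
    w = idx - i0
    valid = (i0 >= 0) & (i0 < len(f_axis) - 1)
    i0c = np.clip(i0, 0, len(f_axis) - 2)
    # gather along the last axis with matching leading indices
    ii, jj = np.meshgrid(np.arange(tvol.shape[0]), np.arange(tvol.shape[1]),
                         indexing="ij")
    ii = ii[..., None]
    jj = jj[..., None]
    out = (1 - w) * tvol[ii, jj, i0c] + w * tvol[ii, jj, i0c + 1]
    out[~valid] = 0
    return out


def fk_migration(
    m: MeasurementVolume,
    c_freespace: float = C0,
    *,
    z0: float = 0.0,
) -> ReconstructionVolume:
    """Confocal Stolt (frequency-wavenumber) migration.

    Treats the diffusion-compensated confocal volume as a wavefield
    recorded at z = 0 and migrates it with velocity c/2 (round-trip time):
    after a padded 3D FFT, the temporal-frequency axis is resampled onto
    the dispersion relation f = (c/2) sqrt(kx^2 + ky^2 + kz^2) with linear
    interpolation and Jacobian amplitude scaling |kz| / sqrt(...), and the
    result inverse transformed. Output depth slice k sits at
    z = z0 + k c dt / 2.
    """
    nx, ny, nt = m.data.shape
    v = c_freespace / 2.0
    dz = v * m.dt
    pad = (2 * nx, 2 * ny, 2 * nt)
    tvol = fftshift(fftn(np.asarray(m.data, dtype=float), s=pad))

    kx = fftshift(fftfreq(pad[0], d=m.grid.pitch))
    ky = fftshift(fftfreq(pad[1], d=m.grid.pitch))
    f = fftshift(fftfreq(pad[2], d=m.dt))
    kz = f / v  # output wavenumber grid reuses the f axis layout

    KX, KY, KZ = np.meshgrid(kx, ky, kz, indexing="ij")
    kmag = np.sqrt(KX**2 + KY**2 + KZ**2)
    f_target = np.sign(KZ) * v * kmag  # Hermitian-symmetric remap keeps output real
    vol_k = _stolt_interp(tvol, f, f_target)
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(kmag > 0, np.abs(KZ) / kmag, 1.0)
    vol_k *= jac
    vol = ifftn(ifftshift(vol_k))
    out = np.abs(vol[:nx, :ny, :nt])
    return ReconstructionVolume(albedo=out,
                                voxel_size=(m.grid.pitch, m.grid.pitch, dz),
                                z0=z0, meta={"method": "fk"})


def _lightcone_psf(nx: int, ny: int, nv: int, pitch: float, dv: float) -> np.ndarray:
    """Discrete light-cone kernel h(dx, dy, w) = delta(w - dx^2 - dy^2).

    Built on the padded grid with the same linear two-bin deposit used by
    the forward model; lateral offsets are centered at (nx//2, ny//2).
    """
    ox = (np.arange(nx) - nx // 2) * pitch
    oy = (np.arange(ny) - ny // 2) * pitch
    w = ox[:, None] ** 2 + oy[None, :] ** 2
    psf = np.zeros((nx * ny, nv))
    idx = (w / dv).ravel()
    i0 = np.floor(idx).astype(int)
    frac = idx - i0
    rows = np.arange(nx * ny)
    ok = i0 < nv - 1
    np.add.at(psf, (rows[ok], i0[ok]), 1.0 - frac[ok])
    np.add.at(psf, (rows[ok], i0[ok] + 1), frac[ok])
    return psf.reshape(nx, ny, nv)


def lct_transform(
    m: MeasurementVolume,
    c_freespace: float = C0,
    *,
    z0: float = 0.0,
    falloff_exponent: float = 2.0,
    cfg: WienerConfig | None = None,
) -> ReconstructionVolume:
    """Light-Cone Transform reconstruction.

    The change of variables v = (c t / 2)^2 (one-way range squared) turns
    the confocal one-bounce model into a 3D convolution with a light-cone
    kernel, inverted here by Wiener filtering, after compensating the
    radiometric falloff r^-falloff_exponent along the cone (2 for
    retroreflective scenes, 4 for isotropic). The result is resampled back
    to a uniform depth axis matching :func:`fk_migration`'s output grid.
    """
    cfg = cfg or WienerConfig()
    nx, ny, nt = m.data.shape
    r = c_freespace * m.times / 2.0  # one-way range per time sample
    data = np.asarray(m.data, dtype=float) * r**falloff_exponent

    v_max = r[-1] ** 2
    nv = nt
    dv = v_max / (nv - 1)
    v_grid = np.arange(nv) * dv
    # resample t -> v (monotone, linear interpolation)
    t_of_v = 2.0 * np.sqrt(v_grid) / c_freespace
    idx = t_of_v / m.dt
    i0 = np.clip(np.floor(idx).astype(int), 0, nt - 2)
    frac = idx - i0
    resampled = (1 - frac) * data[:, :, i0] + frac * data[:, :, i0 + 1]

    psf = _lightcone_psf(2 * nx - 1, 2 * ny - 1, nv, m.grid.pitch, dv)
    center = (psf.shape[0] // 2, psf.shape[1] // 2)
    est_v = _wiener_apply(resampled, psf, center, cfg)

    # back to uniform z: v(z) = z^2
    dz = c_freespace * m.dt / 2.0
    z_rel = np.arange(nt) * dz
    idxz = np.clip(z_rel**2 / dv, 0, nv - 1 - 1e-9)
    k0 = np.floor(idxz).astype(int)
    fz = idxz - k0
    out = (1 - fz) * est_v[:, :, k0] + fz * est_v[:, :, np.minimum(k0 + 1, nv - 1)]
    out = np.abs(out)
    return ReconstructionVolume(albedo=out,
                                voxel_size=(m.grid.pitch, m.grid.pitch, dz),
                                z0=z0, meta={"method": "lct",
                                             "falloff_exponent": falloff_exponent})


def reconstruct(
    m: MeasurementVolume,
    slab: OpticalSlab,
    cfg: WienerConfig | None = None,
    method: str = "fk",
    *,
    max_order: int = 3,
    kernel: DiffusionKernel | None = None,
    lct_falloff_exponent: float = 2.0,
    lct_cfg: WienerConfig | None = None,
) -> ReconstructionVolume:
    """Full inverse pipeline: diffusion deconvolution + confocal inverse filter.

    Builds the two-way diffusion kernel for the measurement grid from the
    slab parameters (calibrated or configured), Wiener-deconvolves it, and
    applies the selected confocal inverse operator. Provenance (slab
    parameters, alpha, method) is recorded on the output.
    """
    if method not in ("fk", "lct"):
        raise ValueError(f"method must be 'fk' or 'lct', got {method!r}")
    cfg = cfg or WienerConfig()
    if kernel is None:
        one_way = sampled_kernel(slab, m.grid.pitch, m.grid.pitch, m.dt,
                                 m.grid.nx, m.grid.ny, m.nt, max_order=max_order)
        kernel = two_way_kernel(one_way)
    compensated = wiener_deconvolve(m, kernel, cfg)
    if method == "fk":
        vol = fk_migration(compensated, C0, z0=slab.z_d)
    else:
        # the light-cone inversion has its own conditioning, independent of
        # the measurement-SNR alpha used for the diffusion deconvolution
        vol = lct_transform(compensated, C0, z0=slab.z_d, cfg=lct_cfg,
                            falloff_exponent=lct_falloff_exponent)
    meta = dict(vol.meta or {})
    meta.update({"mu_a": slab.mu_a, "mu_s_prime": slab.mu_s_prime,
                 "n_medium": slab.n_medium, "z_d": slab.z_d,
                 "alpha": np.asarray(cfg.alpha).tolist(), "max_order": max_order})
    return replace(vol, meta=meta)


def _conv_crop(x: np.ndarray, k: np.ndarray, offsets: tuple[int, int, int]) -> np.ndarray:
    full = fftconvolve(x, k, mode="full")
    ox, oy, ot = offsets
    return full[ox:ox + x.shape[0], oy:oy + x.shape[1], ot:ot + x.shape[2]]


def poisson_likelihood(counts: np.ndarray, lam: np.ndarray) -> float:
    """Poisson log-likelihood up to the data-only log-factorial term."""
    lam = np.maximum(lam, 1e-30)
    return float((counts * np.log(lam) - lam).sum())


def poisson_iterative_reconstruct(
    m: MeasurementVolume,
    kernel: DiffusionKernel,
    iterations: int = 50,
    *,
    dark_per_bin: float = 0.0,
) -> MeasurementVolume:
    """Richardson-Lucy diffusion compensation for photon-count volumes.

    Maximizes the Poisson likelihood of counts under the convolutional
    model counts ~ Poisson(phi_bar * I + dark) with multiplicative updates

        I <- I * [Khat^T (m / (K I + dark))] / [K^T 1],

    which preserve non-negativity and never decrease the likelihood. The
    returned volume is the diffusion-compensated estimate of I (floating
    point); the likelihood trace is stored under meta["loglik_trace"].
    """
    if not m.is_counts:
        raise ValueError("poisson_iterative_reconstruct requires an integer-count volume")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    counts = np.asarray(m.data, dtype=float)
    k = kernel.values / kernel.values.sum()
    kx, ky, kt = k.shape
    fwd_off = (kx // 2, ky // 2, 0)
    adj_off = (kx - 1 - kx // 2, ky - 1 - ky // 2, kt - 1)
    kflip = k[::-1, ::-1, ::-1]

    est = np.full_like(counts, counts.mean() + 1e-12)
    norm = _conv_crop(np.ones_like(counts), kflip, adj_off)
    norm = np.maximum(norm, 1e-12)
    trace = []
    for _ in range(iterations):
        lam = _conv_crop(est, k, fwd_off) + dark_per_bin
        trace.append(poisson_likelihood(counts, lam))
        ratio = counts / np.maximum(lam, 1e-30)
        est = est * _conv_crop(ratio, kflip, adj_off) / norm
        est = np.maximum(est, 0.0)
    lam = _conv_crop(est, k, fwd_off) + dark_per_bin
    trace.append(poisson_likelihood(counts, lam))
    return replace(m, data=est, is_counts=False,
                   meta={**(m.meta or {}), "loglik_trace": trace,
                         "rl_iterations": iterations})


def depth_falloff_compensation(v: ReconstructionVolume, exponent: float) -> ReconstructionVolume:
    """Scale each depth slice by (z / z_ref)^exponent to undo radiometric falloff.

    z_ref is the depth of the nearest slice, so the first slice is left
    unchanged and deeper slices are boosted (for positive exponents).
    """
    if not np.isfinite(exponent):
        raise ValueError("exponent must be finite")
    if exponent == 0:
        return v
    zs = v.zs
    z_ref = zs[0] if zs[0] > 0 else (zs[1] if len(zs) > 1 else 1.0)
    scale = np.power(np.maximum(zs, 0.0) / z_ref, exponent)
    return replace(v, albedo=v.albedo * scale,
                   meta={**(v.meta or {}), "falloff_compensation": exponent})


def max_intensity_projection(v: ReconstructionVolume, axis: str = "z",
                             gamma: float = 1.0) -> np.ndarray:
    """Maximum-intensity projection along an axis, normalized and gamma-mapped.

    Returns a 2D image in [0, 1]; a gamma of 1/3 reproduces the usual
    display stretch for transient reconstructions.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    ax = {"x": 0, "y": 1, "z": 2}.get(axis)
    if ax is None:
        raise ValueError(f"axis must be one of x, y, z; got {axis!r}")
    img = v.albedo.max(axis=ax)
    peak = img.max()
    if peak > 0:
        img = img / peak
    return img**gamma
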