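"""Time-domain diffusion kernel of the scattering slab.

``transmittance_phi`` evaluates the closed-form Green's function for
transmission through the slab (dipole image-source series, extrapolated
boundaries). ``sampled_kernel`` discretizes it onto the scan grid and time
bins, and ``two_way_kernel`` forms the through-and-back kernel
phi_bar = phi * phi (spatio-temporal self-convolution) that the confocal
measurement model convolves with the hidden scene's free-space transient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import irfftn, rfftn

from .slab import DipoleSet, OpticalSlab, default_dipoles

log = logging.getLogger(__name__)


def transmittance_phi(
    t,
    lateral_offset: tuple[float, float],
    slab: OpticalSlab,
    dipoles: DipoleSet,
    *,
    clamp: bool = True,
):
    """Transmitted diffuse flux phi(t, Δx, Δy) through the slab.

    Evaluates

        phi = 1 / (2 (4πDc)^{3/2} t^{5/2})
              · exp(-μa c t - (Δx² + Δy²)/(4Dct))
              · Σ_i [(z_d - z_{+,i}) e^{-(z_d - z_{+,i})²/(4Dct)}
                     - (z_d - z_{-,i}) e^{-(z_d - z_{-,i})²/(4Dct)}]

    in units of power per unit area per unit time (arbitrary linear scale).
    ``t`` may be a scalar or array of times in ns; non-positive times map to
    zero by the closed form's t → 0+ limit.
    """
    t = np.asarray(t, dtype=float)
    dx, dy = lateral_offset
    if not (np.all(np.isfinite(t)) and np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("times and offsets must be finite")

    D = slab.diffusion_coefficient
    c = slab.c
    pos = t > 0
    ts = np.where(pos, t, 1.0)  # dummy for masked lanes

    four_dct = 4.0 * D * c * ts
    pref = 1.0 / (2.0 * (4.0 * np.pi * D * c) ** 1.5 * ts**2.5)
    lateral = np.exp(-(dx * dx + dy * dy) / four_dct - slab.mu_a * c * ts)

    dzp = slab.z_d - dipoles.z_plus  # (n_orders,)
    dzm = slab.z_d - dipoles.z_minus
    ft = four_dct[..., None]
    series = (dzp * np.exp(-(dzp**2) / ft) - dzm * np.exp(-(dzm**2) / ft)).sum(axis=-1)

    out = np.where(pos, pref * lateral * series, 0.0)
    if clamp:
        out = np.maximum(out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class DiffusionKernel:
    """Sampled diffusion response on a (Δx, Δy, t) grid.

    ``values[ix, iy, it]`` holds the flux at lateral offset
    ((ix - nx//2) dx, (iy - ny//2) dy) and time it · dt: lateral offsets are
    centered on zero and the time axis starts at t = 0, where the closed
    form's limit makes the sample exactly zero. Sampling at t = k·dt (rather
    than bin centers) keeps discrete convolution on the same grid, so the
    two-way kernel's temporal centroid is exactly twice the one-way
    centroid. ``two_way`` marks the self-convolved kernel phi_bar.
    """

    values: np.ndarray
    dx: float
    dy: float
    dt: float
    two_way: bool = False
    meta: dict | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[2]) * self.dt

    def offsets(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny, _ = self.values.shape
        ox = (np.arange(nx) - nx // 2) * self.dx
        oy = (np.arange(ny) - ny // 2) * self.dy
        return ox, oy

    def temporal_centroid(self) -> float:
        """Energy-weighted mean arrival time, ns."""
        profile = self.values.sum(axis=(0, 1))
        return float((profile * self.times).sum() / profile.sum())

    def on_axis(self) -> np.ndarray:
        nx, ny, _ = self.values.shape
        return self.values[nx // 2, ny // 2]


def sampled_kernel(
    slab: OpticalSlab,
    dx: float,
    dy: float,
    dt: float,
    nx: int,
    ny: int,
    nt: int,
    *,
    max_order: int = 3,
    dipoles: DipoleSet | None = None,
    **ze_kwargs,
) -> DiffusionKernel:
    """One-way diffusion kernel sampled on the scan grid.

    Lateral offsets are centered on zero (index nx//2 is the on-axis
    column); time samples sit at k · dt with the t = 0 sample zero. Emits a
    warning when the temporal sampling is too coarse to resolve the
    transmitted pulse.
    """
    if min(dx, dy, dt) <= 0 or min(nx, ny, nt) < 1:
        raise ValueError("pitches must be positive and counts >= 1")
    if dipoles is None:
        dipoles = default_dipoles(slab, max_order=max_order, **ze_kwargs)

    ox = (np.arange(nx) - nx // 2) * dx
    oy = (np.arange(ny) - ny // 2) * dy
    t = np.arange(nt) * dt
    rho2 = ox[:, None] ** 2 + oy[None, :] ** 2  # (nx, ny)

    # Evaluate on the full grid in one pass: factor the lateral Gaussian out
    # of the on-axis series.
    on_axis_raw = transmittance_phi(t, (0.0, 0.0), slab, dipoles, clamp=False)
    on_axis_raw = np.atleast_1d(on_axis_raw)
    four_dct = 4.0 * slab.diffusion_coefficient * slab.c * np.where(t > 0, t, 1.0)
    lateral = np.exp(-rho2[..., None] / four_dct)  # (nx, ny, nt)
    values = on_axis_raw * lateral

    neg = values < 0
    clipped_mass = -values[neg].sum()
    clipped_fraction = neg.mean()
    if clipped_mass > 0:
        total = values[~neg].sum()
        log.debug("clamped negative kernel mass: %.3g (%.3g of total)",
                  clipped_mass, clipped_mass / max(total, 1e-300))
    values = np.maximum(values, 0.0)

    peak_idx = int(np.argmax(values[nx // 2, ny // 2]))
    onax = values[nx // 2, ny // 2]
    if onax.max() > 0:
        above = onax > 0.5 * onax.max()
        if above.sum() < 2:
            warnings.warn(
                "diffusion kernel temporally undersampled: pulse FWHM spans "
                f"fewer than 2 bins at dt={dt} ns (peak bin {peak_idx})",
                stacklevel=2,
            )

    meta = {
        "mu_a": slab.mu_a, "mu_s_prime": slab.mu_s_prime,
        "n_medium": slab.n_medium, "z_d": slab.z_d,
        "max_order": len(dipoles.orders) // 2,
        "clamped_mass": float(clipped_mass),
        "clamped_fraction": float(clipped_fraction),
    }
    return DiffusionKernel(values=values, dx=dx, dy=dy, dt=dt, two_way=False, meta=meta)


def two_way_kernel(one_way: DiffusionKernel) -> DiffusionKernel:
    """Spatio-temporal self-convolution phi_bar = phi * phi.

    Computed with zero-padded FFTs (linear-convolution semantics), then
    cropped back to the one-way grid: lateral offsets stay centered on
    zero and the time axis keeps the first nt bins. The convolution sum is
    not rescaled by the bin volume, so the kernel remains in arbitrary
    linear flux units; downstream reconstruction is scale invariant.
    """
    if one_way.two_way:
        raise ValueError("kernel is already two-way")
    v = one_way.values
    nx, ny, nt = v.shape
    full = (2 * nx - 1, 2 * ny - 1, 2 * nt - 1)
    spec = rfftn(v, s=full)
    conv = irfftn(spec * spec, s=full)
    # center crop laterally: zero-offset of phi is at nx//2, so the
    # zero-offset of phi*phi sits at 2*(nx//2); keep a window of nx bins
    # centered there.
    cx = 2 * (nx // 2) - nx // 2
    cy = 2 * (ny // 2) - ny // 2
    out = conv[cx:cx + nx, cy:cy + ny, :nt]
    scale = out.max()
    if not np.isfinite(scale) or scale <= 0:
        raise FloatingPointError("two-way kernel degenerate (zero or overflow)")
    meta = dict(one_way.meta or {})
    meta["two_way_scale"] = 1.0
    if scale > 1e100:  # rescale before downstream squaring overflows
        out = out / scale
        meta["two_way_scale"] = float(scale)
    out = np.maximum(out, 0.0)
    return DiffusionKernel(values=out, dx=one_way.dx, dy=one_way.dy,
                           dt=one_way.dt, two_way=True, meta=meta)


def temporal_fwhm(profile: np.ndarray, dt: float) -> float:
    """FWHM of a sampled temporal pulse with linear edge interpolation, ns."""
    profile = np.asarray(profile, dtype=float)
    peak = profile.max()
    if peak <= 0:
        return 0.0
    half = peak / 2.0
    above = np.nonzero(profile >= half)[0]
    i0, i1 = above[0], above[-1]
    # interpolate the crossing on each flank
    left = float(i0)
    if i0 > 0:
        left = i0 - (profile[i0] - half) / (profile[i0] - profile[i0 - 1])
    right = float(i1)
    if i1 < len(profile) - 1:
        right = i1 + (profile[i1] - half) / (profile[i1] - profile[i1 + 1])
    return (right - left) * dt


def save_kernel(path, kernel: DiffusionKernel) -> None:
    """Write a kernel to an HDF5 file (dataset ``values`` + attributes)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=kernel.values)
        f.attrs["dx"] = kernel.dx
        f.attrs["dy"] = kernel.dy
        f.attrs["dt"] = kernel.dt
        f.attrs["two_way"] = kernel.two_way
        for k, v in (kernel.meta or {}).items():
            f.attrs[k] = v


def load_kernel(path) -> DiffusionKernel:
    """Read a kernel written by :func:`save_kernel`."""
    import h5py

    with h5py.File(path, "r") as f:
        values = f["values"][...]
        attrs = dict(f.attrs)
    dx = float(attrs.pop("dx"))
    dy = float(attrs.pop("dy"))
    dt = float(attrs.pop("dt"))
    two_way = bool(attrs.pop("two_way"))
    return DiffusionKernel(values=values, dx=dx, dy=dy, dt=dt,
                           two_way=two_way, meta=attrs or None)
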