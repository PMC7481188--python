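"""Optical properties of a homogeneous scattering slab.

The slab occupies 0 <= z <= z_d; light enters at z = 0 and the hidden scene
lives in the half-space z >= z_d. Propagation inside the slab is treated in
the diffusion approximation with extrapolated boundary conditions: the
diffusive intensity is taken to vanish on planes a distance ``z_e`` outside
each physical face, which an infinite series of positive/negative image
("dipole") sources enforces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Vacuum speed of light in cm/ns.
C0 = 29.9792458


def effective_boundary_factor(n_medium: float) -> float:
    """Boundary mismatch factor A = (1 + r_d)/(1 - r_d).

    Uses the empirical internal-reflectance polynomial

        r_d = -1.440 n^-2 + 0.710 n^-1 + 0.668 + 0.0636 n,

    a standard tissue-optics fit for the diffuse reflectance at a
    medium–air interface of relative refractive index ``n``. Note the
    polynomial does not vanish exactly at n = 1 (A(1) ≈ 1.003 rather than
    the index-matched value of 1); pass ``r_d_override=0`` to
    :func:`extrapolation_distance` for a strictly index-matched boundary.

    Parameters
    ----------
    n_medium : float
        Refractive index of the slab relative to the surroundings, >= 1.

    Returns
    -------
    float
        Dimensionless factor A >= 1 for n in [1.0, 1.6].
    """
    n = float(n_medium)
    if not np.isfinite(n) or n < 1.0:
        raise ValueError(f"n_medium must be >= 1, got {n_medium!r}")
    r_d = -1.440 * n**-2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


@dataclass(frozen=True)
class OpticalSlab:
    """Slab optical parameters (cm / ns units).

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, cm^-1.
    mu_s_prime : float
        Reduced scattering coefficient, cm^-1.
    n_medium : float
        Refractive index (>= 1).
    z_d : float
        Slab thickness, cm.
    """

    mu_a: float
    mu_s_prime: float
    n_medium: float
    z_d: float

    def __post_init__(self) -> None:
        if not (self.mu_a > 0 and np.isfinite(self.mu_a)):
            raise ValueError(f"mu_a must be positive, got {self.mu_a}")
        if not (self.mu_s_prime > 0 and np.isfinite(self.mu_s_prime)):
            raise ValueError(f"mu_s_prime must be positive, got {self.mu_s_prime}")
        if not (self.n_medium >= 1 and np.isfinite(self.n_medium)):
            raise ValueError(f"n_medium must be >= 1, got {self.n_medium}")
        if not (self.z_d > 0 and np.isfinite(self.z_d)):
            raise ValueError(f"z_d must be positive, got {self.z_d}")

    @property
    def diffusion_coefficient(self) -> float:
        """D = 1 / (3 (mu_a + mu_s')), cm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    # short alias used throughout formulas
    D = diffusion_coefficient

    @property
    def z0(self) -> float:
        """Depth of the equivalent isotropic source, 1/mu_s', cm."""
        return 1.0 / self.mu_s_prime

    @property
    def transport_mfp(self) -> float:
        """Transport mean free path l* = 1/(mu_a + mu_s'), cm."""
        return 1.0 / (self.mu_a + self.mu_s_prime)

    @property
    def c(self) -> float:
        """In-medium speed of light, cm/ns."""
        return C0 / self.n_medium


def extrapolation_distance(
    slab: OpticalSlab,
    *,
    r_d_override: float | None = None,
    z_e_override: float | None = None,
) -> float:
    """Extrapolation distance z_e = 2 A D, cm.

    ``r_d_override`` substitutes the internal-reflectance value (0 gives the
    index-matched z_e = 2D); ``z_e_override`` bypasses the formula entirely.
    """
    if z_e_override is not None:
        if z_e_override <= 0:
            raise ValueError("z_e_override must be positive")
        return float(z_e_override)
    if r_d_override is not None:
        a = (1.0 + r_d_override) / (1.0 - r_d_override)
    else:
        a = effective_boundary_factor(slab.n_medium)
    return 2.0 * a * slab.diffusion_coefficient


@dataclass(frozen=True)
class DipoleSet:
    """Image-source depths enforcing the extrapolated boundary conditions.

    ``z_plus[i]``/``z_minus[i]`` are the positive/negative source depths for
    order ``orders[i]``:

        z_{+,i} = 2 i (z_d + 2 z_e) + z0
        z_{-,i} = 2 i (z_d + 2 z_e) - 2 z_e - z0
    """

    orders: np.ndarray
    z_plus: np.ndarray
    z_minus: np.ndarray
    z_e: float

    def __post_init__(self) -> None:
        if len(self.z_plus) != len(self.z_minus) or len(self.z_plus) != len(self.orders):
            raise ValueError("orders, z_plus, z_minus must have equal length")


def dipole_positions(slab: OpticalSlab, z_e: float, max_order: int = 3) -> DipoleSet:
    """Image-source positions for orders i = 0, ±1, ..., ±max_order.

    The default ``max_order=3`` gives 7 dipole pairs, which truncates the
    infinite series at negligible error for slabs a few transport mean free
    paths thick (see :mod:`cdtomo.diffusion` truncation tests).
    """
    if max_order < 0:
        raise ValueError(f"max_order must be >= 0, got {max_order}")
    i = np.arange(-max_order, max_order + 1)
    period = slab.z_d + 2.0 * z_e
    z_plus = 2.0 * i * period + slab.z0
    z_minus = 2.0 * i * period - 2.0 * z_e - slab.z0
    return DipoleSet(orders=i, z_plus=z_plus, z_minus=z_minus, z_e=float(z_e))


def default_dipoles(slab: OpticalSlab, max_order: int = 3, **ze_kwargs) -> DipoleSet:
    """Convenience: extrapolation distance + dipole set in one call."""
    return dipole_positions(slab, extrapolation_distance(slab, **ze_kwargs), max_order)
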