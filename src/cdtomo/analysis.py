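"""Closed-form system diagnostics: diffusive time scales, resolution
bounds, and validity of the confocal approximation.

The diffusive traversal time dt_d = z_d^2 / (6 D c) sets the temporal
spread a pulse acquires crossing the slab one way; doubling it for the
round trip bounds the axial resolution (dz >= c dt_d) and, through the
scan-aperture geometry, the lateral resolution
(dx >= c sqrt(w^2 + H^2)/w dt_d). The confocal approximation holds in the
paraxial regime when c dt > L^2 / (2H), with worst-case error ~L outside
it, where L is the illuminated-spot extent on the slab's far face and H
the standoff distance to the scene.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .slab import C0, OpticalSlab


def transport_mfp(slab: OpticalSlab) -> float:
    """Transport mean free path l* = 1/(mu_a + mu_s'), cm."""
    return slab.transport_mfp


def traversal_time(slab: OpticalSlab) -> float:
    """One-way diffusive traversal time dt_d = z_d^2 / (6 D c), ns.

    Uses the in-medium speed of light; the transmitted-and-back pulse
    width is approximately 2 dt_d.
    """
    return slab.z_d**2 / (6.0 * slab.diffusion_coefficient * slab.c)


def resolution_bounds(slab: OpticalSlab, H: float, w: float) -> tuple[float, float]:
    """Axial and lateral resolution bounds (delta_z, delta_x), cm.

        delta_z = c dt_d,   delta_x = c sqrt(w^2 + H^2)/w dt_d

    with H the standoff distance and w the scan-aperture half-width. The
    in-medium speed is used for c (the convention that reproduces both
    prototype figures; the free-space choice would raise delta_x by the
    refractive index). delta_x >= delta_z always.
    """
    if H <= 0 or w <= 0:
        raise ValueError("H and w must be positive")
    dt_d = traversal_time(slab)
    delta_z = slab.c * dt_d
    delta_x = slab.c * (w**2 + H**2) ** 0.5 / w * dt_d
    return delta_z, delta_x


def approximation_validity(dt_resolution: float, L: float, H: float) -> tuple[bool, float]:
    """Paraxial validity of the confocal approximation.

    Returns (c0 * dt > L^2 / (2H), worst_case_error = L): the first flags
    whether path-length differences across the illuminated spot stay below
    the system's temporal resolution; the second is the non-paraxial
    worst-case position error.
    """
    if dt_resolution <= 0 or L < 0 or H <= 0:
        raise ValueError("dt_resolution and H must be positive, L >= 0")
    return bool(C0 * dt_resolution > L**2 / (2.0 * H)), L


@dataclass(frozen=True)
class ResolutionReport:
    """Summary of the closed-form diagnostics for one system configuration."""

    l_star: float
    D: float
    dt_d: float
    delta_z: float
    delta_x: float
    H: float
    w: float
    L: float
    paraxial_ok: bool
    worst_case_error: float

    def as_dict(self) -> dict:
        return asdict(self)


def resolution_report(
    slab: OpticalSlab,
    H: float,
    w: float,
    *,
    dt_resolution: float = 0.070,
    L: float | None = None,
) -> ResolutionReport:
    """Assemble the full diagnostic report.

    ``L`` defaults to the slab thickness (diffusive spreading makes the
    illuminated spot scale with z_d); pass the measured spot width to
    override (2.2 cm for the prototype).
    """
    if L is None:
        L = slab.z_d
    dz, dx = resolution_bounds(slab, H, w)
    ok, worst = approximation_validity(dt_resolution, L, H)
    return ResolutionReport(
        l_star=transport_mfp(slab),
        D=slab.diffusion_coefficient,
        dt_d=traversal_time(slab),
        delta_z=dz,
        delta_x=dx,
        H=H,
        w=w,
        L=L,
        paraxial_ok=ok,
        worst_case_error=worst,
    )
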