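"""Deterministic hidden-scene fixtures.

Small voxelized targets emulating the scenes used to exercise the
pipeline: single points, axially separated point pairs, rasterized letter
masks, traffic-cone-like frusta at several depths, and planes. Standoffs
are measured from the slab's far face; the generated scene holds absolute
z coordinates (z_d + standoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import HiddenScene

FIXTURE_KINDS = ("point", "two_points", "letter_mask", "three_cones", "plane")

# 7x7 binary bitmaps, row = y (top first), column = x
_LETTERS = {
    "S": [
        "011110",
        "100001",
        "100000",
        "011110",
        "000001",
        "100001",
        "011110",
    ],
    "U": [
        "100001",
        "100001",
        "100001",
        "100001",
        "100001",
        "100001",
        "011110",
    ],
    "T": [
        "111111",
        "000110",
        "000110",
        "000110",
        "000110",
        "000110",
        "000110",
    ],
}


@dataclass(frozen=True)
class SceneFixtureSpec:
    """Description of a synthetic hidden scene.

    ``standoffs`` are distances behind the slab's far face, cm;
    ``z_d`` locates that face so the scene carries absolute coordinates.
    """

    kind: str
    standoffs: tuple[float, ...] = (50.0,)
    reflectance_model: str = "retroreflective"
    voxel_pitch: float = 2.0
    seed: int = 0
    z_d: float = 0.0
    letter: str = "S"
    lateral_extent: float = 40.0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {FIXTURE_KINDS}")
        if any(s < 0 for s in self.standoffs):
            raise ValueError("standoffs must be >= 0 (measured from the far face)")


def make_fixture(spec: SceneFixtureSpec) -> HiddenScene:
    """Build the deterministic voxel scene described by ``spec``."""
    p = spec.voxel_pitch
    half = spec.lateral_extent / 2.0
    n_lat = max(int(round(2 * half / p)) + 1, 1)
    xs = (np.arange(n_lat) - (n_lat - 1) / 2.0) * p

    if spec.kind == "point":
        albedo = np.ones((1, 1, 1))
        z = spec.z_d + spec.standoffs[0]
        return HiddenScene(albedo=albedo, origin=(0.0, 0.0, z),
                           voxel_size=(p, p, p),
                           reflectance_model=spec.reflectance_model)

    if spec.kind == "two_points":
        if len(spec.standoffs) < 2:
            raise ValueError("two_points needs two standoffs")
        z0 = spec.z_d + min(spec.standoffs)
        z1 = spec.z_d + max(spec.standoffs)
        nz = max(int(round((z1 - z0) / p)) + 1, 2)
        albedo = np.zeros((1, 1, nz))
        albedo[0, 0, 0] = 1.0
        albedo[0, 0, -1] = 1.0
        dz = (z1 - z0) / (nz - 1)
        return HiddenScene(albedo=albedo, origin=(0.0, 0.0, z0),
                           voxel_size=(p, p, dz),
                           reflectance_model=spec.reflectance_model)

    if spec.kind == "letter_mask":
        rows = _LETTERS[spec.letter.upper()]
        mask = np.array([[int(ch) for ch in row] for row in rows])  # (ny, nx)
        ny_m, nx_m = mask.shape
        # rasterize the bitmap onto the voxel grid, letter filling ~60% of extent
        cell = 0.6 * spec.lateral_extent / max(nx_m, ny_m)
        albedo = np.zeros((n_lat, n_lat, 1))
        for iy in range(ny_m):
            for ix in range(nx_m):
                if not mask[iy, ix]:
                    continue
                cx = (ix - (nx_m - 1) / 2.0) * cell
                cy = ((ny_m - 1) / 2.0 - iy) * cell  # bitmap rows go top-down
                sel_x = np.abs(xs - cx) <= cell / 2.0
                sel_y = np.abs(xs - cy) <= cell / 2.0
                albedo[np.ix_(sel_x, sel_y, [0])] = 1.0
        z = spec.z_d + spec.standoffs[0]
        return HiddenScene(albedo=albedo, origin=(xs[0], xs[0], z),
                           voxel_size=(p, p, p),
                           reflectance_model=spec.reflectance_model)

    if spec.kind == "three_cones":
        standoffs = spec.standoffs if len(spec.standoffs) >= 3 else (45.0, 65.0, 78.0)
        z_lo = spec.z_d + min(standoffs)
        z_hi = spec.z_d + max(standoffs)
        nz = max(int(round((z_hi - z_lo) / p)) + 1, 1)
        albedo = np.zeros((n_lat, n_lat, nz))
        centers_x = np.linspace(-half / 2, half / 2, len(standoffs))
        base_r, height = 6.0, 10.0
        for cx, s in zip(centers_x, standoffs):
            z_base = spec.z_d + s
            for kz in range(nz):
                z = z_lo + kz * p
                h = z - z_base
                if not (0 <= h <= height):
                    continue
                r = base_r * (1 - 0.7 * h / height)  # frustum taper
                sel = (xs[:, None] - cx) ** 2 + xs[None, :] ** 2 <= r**2
                albedo[:, :, kz][sel] = 1.0
        return HiddenScene(albedo=albedo, origin=(xs[0], xs[0], z_lo),
                           voxel_size=(p, p, p),
                           reflectance_model=spec.reflectance_model)

    # plane
    albedo = np.ones((n_lat, n_lat, 1))
    z = spec.z_d + spec.standoffs[0]
    return HiddenScene(albedo=albedo, origin=(xs[0], xs[0], z),
                       voxel_size=(p, p, p),
                       reflectance_model=spec.reflectance_model)
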