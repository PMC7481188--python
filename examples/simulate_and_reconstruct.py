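"""Simulate a confocal scan of a hidden letter and reconstruct it.

A retroreflective letter 'S' sits 40 cm behind the scattering slab. The
simulator builds the measurement tau = phi_bar * I (diffusion blur of the
one-bounce transient), and the inverse method undoes it: Wiener
deconvolution of the diffusion kernel, then f-k migration.
"""

import numpy as np

from cdtomo import (
    PROTOTYPE_SLAB,
    InstrumentResponse,
    SceneFixtureSpec,
    WienerConfig,
    make_fixture,
    max_intensity_projection,
    prototype_grid,
    reconstruct,
    simulate_confocal,
)

slab = PROTOTYPE_SLAB
grid = prototype_grid()                      # 32 x 32 points, 70 cm aperture
irf = InstrumentResponse(irf_fwhm=0.070)     # 70 ps combined laser+SPAD

scene = make_fixture(SceneFixtureSpec(kind="letter_mask", letter="S",
                                      standoffs=(40.0,), z_d=slab.z_d,
                                      reflectance_model="retroreflective"))
m = simulate_confocal(scene, slab, grid, irf, dt=0.044, nt=128)
print(f"measurement volume: {m.data.shape}, peak bin at "
      f"{m.data.max(axis=(0, 1)).argmax()} of {m.nt}")

vol = reconstruct(m, slab, WienerConfig(alpha=1e5), method="fk")
x, y, z = vol.argmax_position()
print(f"brightest reconstructed voxel: x={x:.1f} y={y:.1f} z={z:.1f} cm "
      f"(letter plane at z = {slab.z_d + 40.0:.1f} cm)")

mip = max_intensity_projection(vol, axis="z", gamma=1 / 3)
rows = ["".join(" .:*#"[min(int(v * 4.999), 4)] for v in mip[:, j])
        for j in range(mip.shape[1] - 1, -1, -1)]
print("front view (gamma 1/3):")
print("\n".join(rows))
# The ASCII MIP shows the recovered letter; the bright voxel depth agrees
# with the true plane to within the ~9 cm axial resolution bound.
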