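"""Photon-count simulation and Poisson-likelihood deconvolution.

TCSPC measurements are Poisson counts, not Gaussian flux. This script
draws a counts volume for a hidden point target, then compensates the
diffusion blur with Richardson-Lucy multiplicative updates, whose
likelihood is guaranteed non-decreasing.
"""

import numpy as np

from cdtomo import (
    PROTOTYPE_SLAB,
    InstrumentResponse,
    ScanGrid,
    add_poisson_noise,
    point_scene,
    poisson_iterative_reconstruct,
    sampled_kernel,
    simulate_confocal,
    two_way_kernel,
)

slab = PROTOTYPE_SLAB
grid = ScanGrid(nx=16, ny=16, pitch=70 / 31)
irf = InstrumentResponse(irf_fwhm=0.070)
dt, nt = 0.032, 160

scene = point_scene(0.0, 0.0, slab.z_d + 40.0,
                    reflectance_model="retroreflective")
flux = simulate_confocal(scene, slab, grid, irf, dt, nt)
counts = add_poisson_noise(flux, mean_signal_photons=1e5, dark_rate=0.0, seed=3)
print(f"total detected photons: {counts.data.sum():.0f} over "
      f"{grid.nx * grid.ny} scan points")

kernel = two_way_kernel(sampled_kernel(slab, grid.pitch, grid.pitch, dt,
                                       grid.nx, grid.ny, nt))
est = poisson_iterative_reconstruct(counts, kernel, iterations=30)
trace = est.meta["loglik_trace"]
print(f"log-likelihood: {trace[0]:.4g} -> {trace[-1]:.4g} over 30 iterations "
      f"(monotone: {bool(np.all(np.diff(trace) >= -1e-9 * np.abs(trace[0])))})")
peak_t = est.data[8, 8].argmax() * dt
print(f"compensated on-axis peak at t = {peak_t:.2f} ns "
      f"(free-space round trip {2 * 40.0 / 29.9792458:.2f} ns)")
# RL pulls the blurred, delayed pulse back toward the free-space arrival
# time without ever producing negative intensities.
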