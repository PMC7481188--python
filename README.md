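# cdtomo — confocal diffuse tomography

`cdtomo` reconstructs the 3D shape and position of objects hidden behind a
thick diffusive layer (foam, tissue-like slabs, fog analogues) from
time-resolved confocal scans, the measurement a pulsed laser + gated
single-photon detector (SPAD/TCSPC) system produces when it raster-scans
the front face of the scattering medium. It is aimed at researchers in
computational imaging and diffuse optics who want a fully synthetic,
testable twin of such a system: forward simulation, inversion, optical
calibration, and closed-form design diagnostics in one package.

## The model

Light entering the slab (thickness `z_d`, absorption `μa`, reduced
scattering `μs′`, index `n`) is treated in the diffusion approximation
with extrapolated boundary conditions. The time-domain Green's function
for transmission is a dipole image-source series

```
φ(t, Δx, Δy) ∝ t^{-5/2} exp(-μa c t - (Δx²+Δy²)/(4Dct))
               · Σ_i [(z_d - z_{+,i}) e^{-(z_d - z_{+,i})²/4Dct}
                     -(z_d - z_{-,i}) e^{-(z_d - z_{-,i})²/4Dct}]
```

with `D = 1/(3(μa+μs′))`, source depths `z_{+,i} = 2i(z_d+2z_e) + z0`,
`z_{-,i} = 2i(z_d+2z_e) - 2z_e - z0`, `z0 = 1/μs′`, and extrapolation
distance `z_e = 2AD` from the index-mismatch boundary factor `A(n)`.
Seven dipole pairs (`i = 0, ±1, ±2, ±3`) suffice to machine-level series
convergence for slabs a few transport mean free paths thick.

For a confocal scan the measurement factorizes as a 3D convolution,

```
τ ≈ φ̄ ∗ I,     φ̄ = φ ∗ φ,
```

where `I` is the one-bounce free-space transient of the hidden scene.
The inverse applies a Wiener filter in the 3D frequency domain,

```
ρ̂ = A⁻¹ F⁻¹ [ Φ̄̂* / (|Φ̄̂|² + 1/α) ] F τ,
```

followed by a standard confocal inverse operator `A⁻¹` — f–k (Stolt)
migration or the Light-Cone Transform — at `O(N³ log N)` cost. A
Richardson–Lucy variant replaces the Wiener step for Poisson-count data.
Calibration fits `(μa, μs′)` to transmitted pulses through a series of
slab thicknesses, with refractive-index-perturbation uncertainty
intervals; the analysis module gives the closed-form resolution bounds
(`Δz ≥ c·Δt_d`, `Δx ≥ c√(w²+H²)/w·Δt_d`, `Δt_d = z_d²/6Dc`) and the
paraxial validity condition `cΔt > L²/2H`.

## Worked example

`examples/simulate_and_reconstruct.py` hides a retroreflective letter `S`
40 cm behind a 2.54 cm foam slab (μa = 5.26×10⁻³ cm⁻¹, μs′ = 2.62 cm⁻¹,
n = 1.12), scans 32×32 points over a 70 cm aperture, and inverts:

```
measurement volume: (32, 32, 128), peak bin at 78 of 128
brightest reconstructed voxel: x=7.9 y=-5.6 z=44.1 cm (letter plane at z = 42.5 cm)
front view (gamma 1/3): ... (ASCII maximum-intensity projection of the letter)
```

The raw peak sits at bin 78 (≈3.4 ns) because diffusion delays and
smears the 2.7 ns free-space return; after deconvolution and f–k
migration the brightest voxel lands 1.6 cm from the true letter plane,
well inside the ~8.5 cm axial resolution bound. The other scripts in
`examples/` demonstrate the diffusion kernel (`two-way on-axis FWHM =
625 ps` against the predicted `2Δt_d = 633 ps`), the calibration fit
(recovering μs′ to 0.1% from 10⁶-photon curves), photon-count simulation
with Richardson–Lucy compensation, and the resolution report.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
runs the full synthetic pipeline — simulate the hidden-letter scan behind
the prototype slab, add seeded Poisson noise, Wiener-deconvolve the
calibrated diffusion kernel, reconstruct by f–k migration — prints the
recovered peak position and resolution bounds, and writes the report
JSON.
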