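# Methods

This note records the model, the numerical choices, and what the
synthetic tests do and do not establish.

## Coordinate and unit conventions

Lengths in cm, times in ns, `c0 = 29.9792458 cm/ns`. Right-handed
coordinates with z increasing away from the sensor: the slab occupies
`0 ≤ z ≤ z_d`, the scan raster lies on `z = 0`, the hidden scene in
`z ≥ z_d`. Arrays are indexed `(x, y, t)`, 0-based; time axes are
sampled at `t = k·dt` (the `t = 0` sample of the diffusion kernel is
exactly zero by the closed form's limit, and sampling on the lattice
rather than at bin centers keeps discrete convolutions on the same grid,
e.g. the two-way kernel's temporal centroid is exactly twice the one-way
centroid before cropping). Free-space path lengths are measured from the
slab's far face `z = z_d`, which is where the one-bounce transient is
physically anchored; reconstruction depth slices map as
`z = z_d + c0·k·dt/2`.

## Diffusion kernel

The slab Green's function uses extrapolated boundary conditions with
`z_e = 2AD`, where `A = (1+r_d)/(1-r_d)` and `r_d(n) = -1.440 n⁻² +
0.710 n⁻¹ + 0.668 + 0.0636 n` is the standard empirical internal-
reflectance fit. Two caveats are deliberate: the polynomial does not
vanish at `n = 1` (A(1) ≈ 1.003, not exactly the index-matched value),
and published implementations differ in the third decimal of `r_d`, so
kernel values should not be treated as bit-comparable across codes. Both
`r_d` and `z_e` accept overrides.

The image series is truncated at 7 dipole pairs (`max_order = 3`) by
default; at prototype parameters the difference to 11 pairs is below
1e-6 of the kernel peak. The truncated series turns slightly negative in
the far temporal tail (order 1e-7 of peak); these bins are clamped to
zero and the clamped mass recorded in the kernel metadata — it stays
below 1e-6 of the kernel mass, consistent with the truncation error, but
it does affect a few percent of the latest time bins at long windows.

The two-way kernel `φ̄ = φ ∗ φ` is a full spatio-temporal self-
convolution computed with zero-padded FFTs (linear semantics) and
cropped back to the sampling grid. Its on-axis temporal FWHM at
prototype parameters is ~625 ps, matching the diffusive prediction
`2Δt_d ≈ 633 ps`; the laterally integrated profile is wider (~860 ps),
which matters when interpreting per-scan-point pulse widths (a point
target returns light through the whole illuminated patch, so measured
per-point widths track the laterally aggregated kernel).

## Forward model

The confocal fast path evaluates
`τ = φ̄ ∗ I`, with the one-bounce transient `I` deposited by
energy-preserving linear interpolation onto the two nearest time bins.
Reflectance models set the one-way throughput `f`: `1/r²` (isotropic,
confocal falloff `1/r⁴`), `cosθ/r²` (Lambertian, voxel normal facing
the slab), `1/r` (retroreflective, confocal falloff `1/r²` — the
light-efficient case that permits short exposures). Visibility is 1 (no
occlusion); these are the standard confocal transient-imaging choices.
Arrivals later than the recorded window — possible for far off-axis scan
points viewing deep targets — are simply not histogrammed, as in a real
gated acquisition; a voxel whose on-axis return misses the window is an
error.

The brute-force model drops the confocal approximation: for each scan
point the exit plane is sampled on a patch of side 3× the illuminated
spot width (default 2.2 cm) and all pairs `(r1, r2)` of exit samples are
accumulated through `φ ∗ I ∗ φ`. The pairwise double sum factorizes as
the square of a single sum per voxel in the temporal frequency domain,
which keeps the oracle usable at 8×8 scan grids. Exit samples carry an
area weight `(resolution/pitch)²` so amplitudes are directly comparable
with the fast path. On a point target at 50 cm the two models agree in
energy to a few percent and the relative L2 discrepancy falls as the
standoff doubles — the validity trend of the confocal approximation.

The instrument model lumps the laser pulse (~35 ps) and detector jitter
into one Gaussian IRF of 70 ps FWHM, applied as a zero-delay temporal
blur; gating zeroes bins before the gate time; photon noise scales the
expected flux to a per-scan-point budget and draws Poisson counts from
an explicit seed (no hidden RNG state anywhere in the package).

## Inversion

Wiener deconvolution operates on the zero-padded 3D spectrum (pad factor
2 for linear semantics). `alpha` is relative by default: the filter
denominator is `|Φ̄̂|² + max|Φ̄̂|²/α`, making reconstruction invariant to
kernel and measurement scale. The default `α = 10` (noise floor at a
tenth of peak kernel power) suits photon-limited data; noiseless
synthetic studies use large α (1e5–1e12). The kernel's onset delay is
part of its phase, so deconvolution automatically removes the bulk time
delay of the scattering layer; no separate trimming is applied (a
deliberate choice — trimming would change the conditioning, not the
model).

f–k migration treats the compensated volume as a wavefield with
round-trip velocity `c/2`: padded 3D FFT, linear (Stolt) resampling of
the temporal frequency onto `f = (c/2)√(kx²+ky²+kz²)` with Hermitian-
symmetric sign handling and Jacobian `|kz|/|k|`, inverse FFT, magnitude.
The Light-Cone Transform alternative squares the range variable
(`v = (ct/2)²`), inverts the resulting light-cone convolution by Wiener
filtering, and resamples back to uniform depth; its radiometric
pre-weighting `r^p` uses `p = 2` (retroreflective) by default, `p = 4`
for isotropic scenes. The LCT's internal cone inversion is conditioned
independently of the diffusion-deconvolution α — inheriting a large
noiseless-regime α there amplifies window-edge artifacts.

For count data, a Richardson–Lucy scheme maximizes the Poisson
likelihood under the convolutional model with multiplicative updates;
non-negativity is preserved by construction and the log-likelihood trace
(recorded in metadata) is asserted non-decreasing. This is an
interpretation: it honors the stated likelihood model, not a specific
published update rule.

## Calibration

`(μa, μs′)` are fitted jointly to transmitted pulses at 15 thicknesses
(2.54–20.32 cm, 1.27 cm steps). Per-curve amplitudes are linear and
solved in closed form at each candidate, which removes the scale
degeneracy from the nonlinear search; a single shared time offset `t0`
absorbs trigger alignment. The search is a derivative-free simplex in
`(log μa, log μs′, t0)` from 5 starts (log-space bounds μa ∈ [1e-4, 1],
μs′ ∈ [0.1, 100] cm⁻¹); the stopping rule is relative (1e-10 of the
starting SSE) because the residual floor of Poisson data is data-scale
dependent. Loss is unweighted squared error on counts; a fit from one
thickness runs but is flagged weakly identified. Synthetic curves
auto-window to ~4× their own diffusion peak time — thick slabs need tens
of ns — and default to 10⁶ photons per curve, a realistic TCSPC
exposure. Uncertainty intervals come from refitting over a uniform
21-point refractive-index grid spanning ±10% of the nominal n = 1.12
(1.008–1.232) and taking the central 95% of the optimized values.

## Resolution diagnostics

`Δz ≥ c·Δt_d` and `Δx ≥ c√(w²+H²)/w·Δt_d` use the in-medium speed of
light: that convention reproduces both prototype figures (~9 cm axial,
~15 cm lateral at H = 50, w = 35) within a few percent, whereas the
free-space speed misses the lateral figure by ~10%. The ambiguity is
real and documented rather than hidden; the choice only rescales both
bounds by n. The paraxial validity check `c0·Δt > L²/2H` uses the
free-space speed (the path-length differences it bounds are in air). The
illuminated-spot extent `L` defaults to the slab thickness, the
diffusive-spreading scaling, and can be overridden by a measured value.

## What the synthetic world does and does not establish

The generators emulate the prototype: 32×32 scan points over a 70 cm
aperture, 128-bin histograms, 70 ps IRF, the foam slab coefficients, and
scenes (letters, axially separated pairs, cone-like frusta at 45/65/78
cm) mirroring the captured ones. The time-bin width is not published;
0.032 ns is the default, and window lengths are chosen so the scene plus
kernel spread fit (the demo uses 0.044 ns × 128 bins for a 40 cm letter
for exactly this reason — at 0.032 ns the corner-of-aperture returns of
a 50 cm scene fall off the window and their truncation rings through the
deconvolution). Green tests establish internal consistency of the
forward/inverse pair, agreement of the diffusion model with an
independent Monte Carlo random walk (peak time, pulse width, thickness
trends), and parameter identifiability under Poisson noise. They do not
establish agreement with any captured dataset: real measurements add
detector afterpulsing, pile-up, background light, calibration drift, and
scene BSDFs outside the three idealized models, none of which are
simulated here.

## Known limitations

Homogeneous slabs only (no layered or laterally varying media); single
object bounce; no occlusion; no dead-time or pile-up modeling; the `r_d`
polynomial is an empirical fit whose low-n behaviour is approximate; the
LCT depth resampling loses sub-bin accuracy near `z = z_d` where the
`v = z²` grid is coarse.
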