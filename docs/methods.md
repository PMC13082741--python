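# Methods

## Optical forward model

All polarization optics are expressed in Mueller calculus on Stokes vectors
(S0, S1, S2, S3). The instrument chain is

    camera ← Polarizer2(0°) ← LCVR2(fast 45°, δ2) ← LCVR1(fast 0°, δ1)
           ← sample ← Polarizer1(45°) ← unpolarized source

Element forms: the frame rotation acts on (S1, S2) with
S2′ = −sin 2θ·S1 + cos 2θ·S2; the ideal linear polarizer at axis a is
R(−a)·P₀·R(a) with P₀ the standard half-transmitting projector; the linear
retarder at fast axis 0 maps (S2, S3) by S2′ = cos δ·S2 − sin δ·S3,
S3′ = sin δ·S2 + cos δ·S3. Two conventions are free in this algebra (frame
rotation sense and retarder handedness). Both are pinned by one physical
requirement: the LCVR setting (δ1, δ2) = (0, π/2) must act as a
*right*-circular analyzer, so that 2·Irc − (Ih + Iv) returns +S3. With the
forms above this holds without further sign patches, and the test suite
verifies every element against an independent Jones-calculus conversion
(M = A (J ⊗ J*) A⁻¹ with the Jones retarder diag(e^{−iδ/2}, e^{+iδ/2})).

With these conventions the four canonical settings (0,0), (0,π), (π/2,π/2),
(0,π/2) project exactly (S0±S1)/2, (S0+S2)/2, (S0+S3)/2, making the
four-measurement reduction algebraically exact: the round-trip
simulate→reconstruct error is at machine precision (tested at 1e-10 over
1000 random physical states).

Assumptions: ideal, lossless, wavelength-independent retarders (real LCVRs
disperse; a per-band retardance table can be passed to `psa_matrix` by
constructing non-canonical `PSAConfig`s); ideal polarizers; no objective
polarization aberrations; flat unit illumination spectrum.

## Sample and phantom model

Each pixel/band is a Mueller matrix
t(x,y,λ) · diag(1, d, d, d) · LR(axis, δ): transmittance, isotropic partial
depolarization and an optional weak linear retarder. This is the minimal
passive model producing contrast in all of DOP, DOLP and DOCP. The
depolarization factor d *is* the DOP of the exiting light when the input is
fully polarized, which makes masked-mean DOP an unbiased readout of d and
underlies the monotonicity test.

The phantom generator places non-overlapping ellipses (rejection sampling
with a 2-px exclusion halo; a clear `RuntimeError` if placement fails)
of three morphological classes:

| class | morphology | depolarization (default mean ± between-cell SD) |
|---|---|---|
| granulocyte-like | granules: dilated random points at `granule_density`, depolarization raised by up to `granule_depolarization_contrast` | 0.50 ± 0.05 |
| lymphocyte-like | dense nucleus filling the cell; Gaussian-correlated surface texture (amplitude 0.1) in d and a weak retardance (≲0.1 rad) with smoothly varying axis | 0.30 ± 0.05 |
| monocyte-like | 25% larger ellipse, 2–3 overlapping nuclear lobes (offset set by `nucleus_lobedness`) with strong absorption | 0.40 ± 0.05 |

All stained structures share a transmission spectrum
T(λ) = 1 − 0.55·exp(−((λ−535)/40)²) scaled by a per-pixel chromatin
density (background 0, cytoplasm 0.35–0.65, nuclei 0.65–0.8, granules
0.65), giving the characteristic Romanowsky-stain transmission minimum in
the 520–550 nm window. The band grid defaults to 29 bands, 470–750 nm at
10 nm. The background is modeled as fully depolarizing (exit DOP 0), so
cells stand out in DOP/DOLP/DOCP maps with the contrast direction the
instrument is designed to show; d is wavelength-independent by default, so
phantom DOP spectra are flat apart from noise — class *separation*, not
spectral shape, is what the phantom calibrates.

Detector noise defaults to Gaussian with σ = 1% of full scale (the maximum
intensity over the four noiseless analyzer cubes), applied independently
per analyzer image; Poisson shot noise at a configurable photon budget is
available. All randomness flows from `numpy.random.default_rng(seed)`;
scenes and acquisitions are pure functions of (spec, seed).

## Reconstruction policies

Reconstruction itself is exact and linear; the degeneracies live in the
derived ratios. `compute_derived` masks pixels with S0 at or below a floor
(default 1e-3 × the 99th-percentile S0 — dark-background pixels where the
ratio is meaningless) and clips ratios above 1 (clip/flag/allow policies,
clipped pixels counted, never silently discarded). Noise pushes ~0.01% of
pixels of the standard noisy phantom outside the physical cone, essentially
all at nearly fully polarized granule pixels; `physicality_report`
quantifies this per band without mutating data. Note that clipping breaks
the DOP = √(DOLP² + DOCP²) identity only at clipped pixels; everywhere else
it holds to 1e-12.

## RGB synthesis

Channels are band-weighted sums of the cube against three response curves,
by default Gaussian-lobe analytic approximations of the CIE 1931 color
matching functions (Wyman–Sloan–Shirley fits), clipped to nonnegative and
normalized to unit sum on the band grid — "eye-like" without tabulated
observer data, and guaranteeing that a spectrally flat cube renders gray.
The weighted sum is linear; display normalization (default: per-channel
99th-percentile clip, robust to hot pixels) is the only nonlinear step.
Signed planes (S1–S3) are affine-shifted to [0,1] per plane with the shift
recorded in provenance. NaNs route to an invalid-pixel mask, never into the
image.

## Spectral statistics

A cell's signature is the per-band arithmetic mean over its binary ROI;
background pixels are excluded entirely, so the estimate is invariant to
anything outside the mask. Group comparison is a two-sided two-sample
t-test per band on the per-cell means (one number per cell per band; pixels
are never pooled across cells, which would fake sample size). Welch's
unequal-variance form is the default — robust when per-class variances are
unknown — with pooled-variance Student's t behind `equal_var=True`. Raw
p-values are the primary output; Benjamini–Hochberg adjusted values can be
attached alongside. Identical groups yield t = 0/0, reported as p = 1 (no
evidence against the null). Extremum finding uses three-point comparison on
interior bands, attributing flat-run ties to the shortest wavelength.

Calibration: under a null design (30 cells from one class distribution,
split 15/15, full phantom → acquisition → reconstruction per rep) the
per-band rejection rate at α = 0.05 is ≈ 0.05 over 500 reps. Because each
cell's depolarization draw is shared across bands, p-values are strongly
correlated *across bands within a rep*; the marginal per-band rate is
nevertheless the nominal α, which is what the calibration test measures.

## Problem sizes

Validation experiments run on deliberately small fields: the statistics act
on per-cell mean values, so beyond a few hundred pixels per cell the field
size only changes runtime, not the distribution of the statistic. Defaults:
160×160 px for the showcase phantom; 128×128 px, cells of radius 4–6.5 px
for the 15-vs-15 discrimination study; 112×112 px for the 500-rep null
calibration. The discrimination study generates one scene per class with
independent noise realizations.

## Known limitations

- No LCVR dispersion, polarizer leakage, or calibration error models; the
  simulator validates the reduction pipeline, not a hardware error budget.
- The phantom's depolarization is spectrally flat and its textures are
  statistically stationary within a cell — real cells have structured,
  wavelength-coupled scattering, so passing tests demonstrate pipeline
  correctness and statistical calibration, not biological fidelity of the
  spectra themselves.
- The broadband RGB-camera mode treats R/G/B as three labelled bands
  through the identical reduction; no attempt is made to model real channel
  response overlap in reconstruction.
- Mueller-matrix (16-element) imaging of the sample, Lu–Chipman
  decomposition and angle-of-polarization maps are out of scope — the
  instrument measures Stokes vectors only.
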