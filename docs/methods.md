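# Methods

This note documents the models, conventions and numerical choices behind
`obliquescale`, in the order of the processing chain. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic population model

The generator produces seeded populations that emulate brain-wide
nuclear-calcium recordings: N cells at 1 Hz for `duration` seconds, with a
power-law decay of mean pairwise correlation over distance, a controlled
number of shared latent dimensions, and GCaMP6s-like kinetics.

**Positions.** Uniform inside the ellipsoid inscribed in `brain_extent`
(default 2200 × 1200 × 650 μm, the bounding box of an adult *Danionella*
brain).

**Shared activity.** A linear latent-factor model
`shared = latents @ loadings`. Latent time series are white noise passed
through a first-order exponential (calcium) filter with time constant
`calcium_tau` (default 4 s), then standardized: temporally smooth, unit
variance, autocorrelation time ≈ τ.

**Loading maps.** Each factor's loading over cells is a Gaussian random
field realised with 8 random Fourier features (frequency draws
ω ~ N(0, I/ℓ²) give the exact Gaussian covariance exp(−d²/2ℓ²) in
expectation). Correlation lengths ℓ come from a fixed log-spaced grid
(5–5000 μm, 16 scales). Per-scale variance weights w_s are calibrated at
construction by non-negative least squares so that
Σ_s w_s·exp(−d²/2ℓ_s²) ≈ (d/10 μm)^(−`decay_exponent`) on a log-spaced
distance grid (10–1500 μm); because noise and private activity scale all
correlations by a common factor, the *slope* of the log–log decay is
preserved at the configured exponent.

Two refinements matter for the latent-dimensionality statistics:

- *Degrees-of-freedom cap.* A field with correlation length ℓ has only
  ≈ Π_axis(1 + L/ℓ) independent spatial degrees of freedom over a brain of
  extent L. Factor counts per scale follow the variance weights but are
  capped at max(8, dof); otherwise long-range scales would spend tens of
  factors on mutually collinear (near-constant) maps that add no effective
  dimensionality.
- *Per-scale variance pinning.* Each scale's factor block is rescaled so its
  realised mean-square loading equals the calibrated weight. For long
  scales (few dof) this pins the long-range correlation plateau, which would
  otherwise vary strongly between realisations and make the fitted exponent
  a high-variance draw.

**Private activity and noise.** A fraction `private_fraction` (default 0.2)
of the clean variance is cell-private: calcium-filtered noise uncorrelated
between cells. This bounds the population-explainable variance the way real
recordings are bounded (much of a cell's activity is not predictable from
the rest of the population) and lowers correlation amplitudes to realistic
values without touching the decay slope. White Gaussian noise (`noise_sd`,
default 15% ΔF/F) is added on top. The mean clean per-cell SD is fixed at
25% ΔF/F. With these defaults roughly 55% of the total variance is shared,
20% private and 25% white noise, and bi-cross-validated regression explains
~30–35% of held-out variance.

**Movies.** Nuclei are rendered as 3D Gaussian blobs (lateral FWHM 5 μm,
axial 10 μm) whose brightness follows the clean traces, on the sheared
acquisition grid (plane k displaced by `slope_s · k` native y pixels). A
multiplicative quasi-periodic faceplate pattern, additive camera background,
Poisson noise at 5 e−/count gain and Gaussian read noise are applied;
optional rigid motion is a smooth seeded random walk returned as ground
truth.

**What the generator does not emulate.** No spiking or biophysical model
(latents are Gaussian); no depth-dependent attenuation or scattering; no
anatomical structure beyond the ellipsoid; movie motion is rigid only.
Passing tests therefore demonstrate the correctness and calibration of the
analysis chain on data with the stated covariance structure, not performance
on every artefact of real recordings.

## Unshearing

The sheared stack lives on axes (x, y′, z′); the unsheared lateral
coordinate is y = y′ + s·z′. Resampling onto the orthogonal output grid
(default 0.75 × 1.0 × 4.5 μm³) uses the kernel

    w(j, k) = tri((k − z)/w_z) · ½ [ tri(y − j − s·k) + tri(y − j + 1 − s·k) ]

with tri(x) = max(0, 1 − |x|), evaluated in sheared index units (j, k are
native y′/z′ indices; y, z are the output voxel centre positions converted
to those units; w_z = max(|s|, 1) planes). Each output voxel is renormalized
by its local kernel mass, so partial support at volume borders does not dim
the result and the intensity density of smooth content is conserved to ~1%.

The two-tap ½[tri(·) + tri(· + 1)] lateral kernel averages adjacent
sub-pixel phases along the shear line; as a consequence the literal kernel
is not the identity even on a matched grid when s = 0. Since zero shear
means there is nothing to unshear, s = 0 is treated as plain trilinear
resampling (exactly the identity on a matched grid). Voxel centres sit at
(index + ½)·pitch throughout; volumes are stored [z, y, x] with x fastest.

## Richardson–Lucy deconvolution

Standard multiplicative updates, default 10 iterations, with *periodic*
(FFT) convolution. Periodic boundaries make the scheme exactly
flux-conserving, make any flat image a fixed point for any normalized PSF,
and make a delta PSF the identity — properties zero-padded implementations
violate at the borders. The PSF is user-supplied (an empirical bead average
in practice; `gaussian_psf` provides a parametric stand-in with the system's
FWHM defaults of 2.8 × 2.4 × 13.2 μm). The iteration count is configurable
because the useful number depends on SNR.

## Motion correction

Both template (default: the middle frame) and moving volume are band-passed
with a difference of Gaussians (σ₀ = 2 px, σ₁ = 5 px). Non-overlapping
blocks (coarse default 604 × 192 × 28, fine 32 × 32 16 voxels XYZ; blocks
under 8 px are rejected) are compared by *zero-padded* FFT cross-correlation
normalized per lag by the overlap volume — circular correlation is biased
toward zero lag when the block content is not periodic — with the peak
searched within a quarter-block radius and refined per axis by a 3-point
parabola (clipped to ±½ voxel). Blocks with peak correlation below 0.2 are
dropped from the fits. A global 3×4 affine is least-squares fitted to the
coarse field (requires ≥ 4 non-collinear valid centres); the fine field is
interpolated trilinearly on the block-centre lattice with nearest
extrapolation at borders; the compound transform is applied with trilinear
interpolation, zero-filled out of bounds.

Frames are excluded when the absolute first difference of the registration
metric (global Pearson correlation to the template) exceeds 1.5 SD of all
first differences; the frame *after* each flagged transition is marked. The
rule is invariant to affine rescaling of the metric. Excluded frames are
dropped before baseline filtering and masked (NaN) in stored tables.

## Segmentation and ΔF/F

The local-correlation map is the per-voxel mean Pearson correlation with the
26-connected neighbours (border voxels average their existing neighbours;
zero-variance voxels contribute 0). It is DoG-filtered (σ₀ = 1, σ₁ = 4 px);
local maxima are detected with a 5 μm *minimum separation* — two peaks
closer than one nucleus diameter are duplicates — thresholded at a global
level (default: the 99th percentile of the filtered map, configurable, since
an absolute threshold is a per-dataset visual choice), and refined to
sub-voxel positions by the intensity-weighted centroid of the positive DoG
response within one nucleus radius.

Traces are normalized-Gaussian-footprint means (FWHM 5 μm). The baseline is
median (7 s) → minimum (101 s) → Gaussian (σ = 101 s) filtering with
reflected boundaries, windows converted to samples at the volume rate;
ΔF/F = (F − baseline)/baseline in percent, then mean-centred per cell
(centring by the mean; the alternative median-centring differs negligibly
for these traces). Cells with a non-positive baseline anywhere are invalid.
QC keeps cells whose periodogram power ratio (mean power below 0.25 Hz over
mean power at/above it, mean-removed) is ≥ 1.3 and whose ΔF/F stays within
−100%…2000%. Display order is the leaf order of Ward clustering on
correlation distance (1 − r).

## Correlation-vs-distance analysis

All unique cell pairs enter log-spaced distance bins (default 30 bins over
5–2000 μm) plus explicit underflow/overflow bins, so the pair count always
totals n(n−1)/2. Negative correlations are averaged as-is. The decay
exponent is the magnitude of the least-squares slope of log(mean r) vs
log(bin centre) over 20–1000 μm (bin centres are geometric midpoints;
non-positive bin means are dropped with a warning). Above 10⁷ pairs a
seeded random cell subset is used — an unbiased estimator of the bin means.
Radius-voxelization replaces each cell's trace by the mean over all cells
within the radius (itself included); the secondary correlation compares
cell-pair and voxel-pair coupling values at identical pair indexing.

## Prediction

Timepoints are split per 5-minute block: first 3 min train, 1 min
validation, 1 min test (60/20/20% overall; a trailing partial block is
divided proportionally). Cells are split into target folds (10% each);
predictors are built from the complementary 90% as random cells,
non-overlapping cubic grid voxels (origin-anchored, half-open bins, mean
trace per non-empty bin) or spatially shuffled voxels (cell-to-coordinate
assignment randomized before voxelization).

Ridge coefficients are (XᵀX + αI)⁻¹XᵀY on training timepoints. Predictors
and targets are centred with training means; the predictor matrix is
globally rescaled to the average SD of the raw dataset so a single α grid
serves all predictor types. The grid is 7 log-spaced multipliers
(10⁻²…10⁴) of (mean predictor variance × T_train); α is chosen by
variance-weighted R² on the validation set and performance is reported on
the test set only — the selection never sees test data by construction.
Per-cell R² = 1 − SS_res/SS_tot with SS_tot computed on the held-out
segment itself, and the brain-wide summary is the variance-weighted mean
(weights = held-out variance per cell).

Bi-cross-validated PCR: principal components of the predictor cells on
training timepoints; held-out cells regressed on the leading component
scores by ordinary least squares (scores are orthogonal on the training
set, so the R² curve over component counts is computed incrementally);
evaluation on test timepoints. The dimensionality readout is the smallest
component count whose curve value is within 1% of the maximum (the curve
declines slowly past its maximum from OLS overfitting, so the readout is a
lower bound). With the default generator the readout is ≈300–310 for 400
configured factors: the finite effective temporal sample count
(T/(2τ) ≈ 285 at 2280 samples and τ = 4 s) spreads the realised factor
strengths, and the weakest tail falls inside the 1% band. Averages over ≥3
cell-split seeds are reported.

## Population geometry

The 50/50 protocol: a seeded half of the cells forms the reference space;
reduced spaces are K subsampled cells, or K subsampled grid voxels built
from the held-out half, at matched K. Distortion stress uses Euclidean
distances between all timepoint pairs, Σ(D − k·D_red)²/ΣD² with the
least-squares scale k = ΣD·D_red/ΣD_red²; similarity is the Pearson
correlation between the unique off-diagonal entries of the two time-by-time
correlation matrices (the diagonal is degenerate; timepoints with constant
population vectors are dropped with a warning). Ratios are aggregated as
the mean over matched (seed, count, voxel size) conditions. Above 3000
timepoints a seeded subsample caps the T×T matrices; the desk default
(2280) uses all.

A known desk-scale behaviour: with raw noisy traces as the reference, a
subsampled-cell reduced space shares the reference's per-channel
noise/private-variance proportions exactly, while voxel averaging suppresses
them and filters fine-scale shared signal, so cells here distort *less*
than voxels (cell/voxel stress ratio ≈ 0.8 rather than slightly above 1).
The effect is insensitive to the noise level and to the private fraction;
at desk-scale density 50 μm voxels mostly contain a single cell, which also
pushes the small-voxel conditions toward ratio 1. The similarity ratio
(≈ 0.93) is not affected. See the repository's test suite for the asserted
bands.

## Problem sizes

The desk-scale defaults — 3,000 cells, 2,280 timepoints, 400 latent
factors, 64×48×16-voxel movies for image-chain tests — were chosen so the
full suite and the acceptance script each complete in a few minutes on one
CPU while keeping every statistic estimable (≥10³ pairs per distance bin,
≥400 non-empty voxels at 50–150 μm, ≥5 seeds per stochastic comparison).

## Known limitations

- The unshearing kernel's z-width parameter equals the shear slope as
  printed in the interpolation formula; other widths would trade z
  resolution against noise and are not explored.
- Registration estimates translations per block; rotations appear only
  through the affine fit, and the non-rigid field is piecewise-trilinear.
- The spectral QC assumes a 0.25 Hz split frequency, meaningful only for
  volume rates well above 0.5 Hz.
- The PCR dimensionality readout depends on the 1%-of-maximum convention;
  other conventions (e.g. first maximum) give systematically different
  numbers.
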