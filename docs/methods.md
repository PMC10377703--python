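# Methods

## Data model

An image is an H×W×11 stack in the fixed channel order U1b, U1g, U2b, U2g,
U2r, BLb, BLg, BLr, GRb, GRg, GRr — blue/green/red planes of each filter
cube, high to low excitation wavelength, with the U1 red plane removed
because it carries the Rayleigh reflection of the UV excitation band.
Channels acquired under visible excitation at or below the excitation band
(BLb, GRb, GRg) carry no fluorescence but are kept as a baseline reference,
so every pixel's pseudospectrum has the same 11 coordinates. Intensities
are 14-bit (0–16383) as acquired; all statistics are computed in float64
regardless of storage type. Stacks are stored as multi-page TIFF with the
channel names in the description tag and the group/internode/section
metadata in a sidecar JSON (TIFF tag dialects are too unreliable to carry
study metadata).

## ROI segmentation

Section pixels are separated from background on the sum of the 11 channels.
The sum image is thresholded by Otsu's criterion on a 256-bin histogram of
its [min, max] range (deterministic: ties broken towards the lowest level),
holes — cell lumina and vessels darker than the walls — are filled in the
binary mask, then a binary opening with a disk of diameter 101 px removes
debris and a closing with a disk of diameter 51 px smooths the outline.
"Sizes 101 and 51" are taken as diameters (radii 50 and 25): odd diameters
give centred, symmetric structuring elements. Whether holes are filled
before or after thresholding is configurable (`fill_order`); the default
fills the binary mask after thresholding, the alternative fills grey-level
holes by morphological reconstruction first. Either way the contract is a
solid section mask. A user threshold override is supported for visual
checking. Disk footprints use scikit-image's sequence decomposition
(a fast composition of small structuring elements closely approximating the
disk); opening/closing idempotence holds exactly for the composite element,
and the exact disk is available via `decomposition=None`.

## Streaming PCA

Per image i, over ROI pixels only: the count n_i, channel sums s_i and
cross-products V_i = X_iᵀX_i. These merge by addition, so the global mean
and covariance — and hence the eigen-decomposition — are independent of how
the pixel set is split into images and of streaming order (up to float
summation order, which is fixed to manifest order for bit-reproducibility).
The 11×11 covariance is decomposed with a symmetric eigensolver; no
truncated or randomised methods are needed at this dimension — the
streaming is in the accumulation, not the decomposition.

Numerical choices:

- Covariance normalisation divides by n (population form, `ddof=0`);
  loadings are unaffected by the choice and `ddof=1` is available.
- Loading signs are arbitrary in PCA; each column is flipped so its
  largest-magnitude entry is positive. (On real tissue data the first
  loading then has all-positive entries on an all-one-signed intensity
  axis; analyses that print it with the opposite sign are equivalent.)
- Eigenvalues within 1e-12 (relative) below zero are clipped to 0 — the
  covariance is PSD and such values are floating-point noise.
- Degenerate input (zero total variance) returns a flagged model with all
  λ = 0 and a warning rather than an error.
- Scores are stored as float32 (single precision suffices for 14-bit data
  spread over ±25σ); non-ROI pixels carry NaN in float storage and 0 in
  8-bit renderings.

## Score scaling: σ = √λ

Score renderings span ±5σ and histogram grids ±25σ for a common scale
across the series. σ is derived from the component eigenvalue; since the
eigenvalue of a covariance is the score variance, the default is
σ = √λ, the score standard deviation. The literal statistic σ = λ is
retained as an option (`scale_stat="eigenvalue"`) for compatibility with
conventions that use singular values directly; with λ ≫ 1 it spreads the
±25σ span so far that nearly all scores fall into one or two of the 10,000
raw bins and percentile rebinning degenerates, which is why it is not the
default. The 8-bit coding maps [−5σ, +5σ] linearly to [0, 255]
(configurable `out_max`), clips outside values and rounds half-up, so a
zero score codes to 128.

## Score distributions and percentile rebinning

Step 1, during scoring: each image's component scores are binned on 10,000
equal-width bins spanning ±25σ. Bins are left-closed/right-open with the
last bin closed. Scores beyond the span are clamped into the terminal bins
and reported, so counts always sum to the ROI pixel count; the factor 25
makes overflow rare, and a manual second pass with wider edges is the
remedy if a report shows substantial clamping (retroactive re-binning would
break the single-pass contract).

Step 2, post-processing: the per-image histograms are summed into the total
distribution; its cumulative curve, treated as piecewise linear between the
raw edges, is inverted at 0, 1, …, 100% of the total mass. Where
percentiles fall in an empty score range the leftmost attainment is kept,
yielding repeated edges and zero-width, zero-mass bins that the downstream
PCA tolerates. Each image's cumulative histogram is interpolated at the
percentile edges; successive differences give 100 masses per image,
normalised to fractions by default (images differ in pixel count; raw-count
mode is retained). By construction the count-weighted mean of the
normalised rows is flat at 0.01 per bin up to one raw-bin mass of
interpolation error.

## Group comparison

The images × 100 matrix per component is analysed by a column-centred,
unscaled (covariance) PCA, consistent with the pixel-level analysis;
correlation mode is deliberately not offered because the bins share one
scale. The group effect on each of the first 5 distribution PCs is tested
by one-way ANOVA with the explicit sum-of-squares decomposition
F = (SS_b/df_b)/(SS_w/df_w) and an F(df_b, df_w) upper-tail p-value.
Unbalanced groups are allowed. Raw p-values are reported; a
Benjamini–Hochberg column is emitted alongside, labelled as an extension,
because the table contains components × PCs simultaneous tests. With few
observations and strong ties, the exact permutation distribution of F is
coarse and need not match the F distribution closely; the analytic p-value
is validated against a permutation oracle on continuous data of moderate
size. Nesting of sections within internodes is not modelled (plain one-way
ANOVA on images is the contract); with internode-level variance present,
sections of the same internode are correlated and the test is
anticonservative — a limitation to keep in mind for designs with strong
internode effects.

## Synthetic section simulator

The phantom emulates an internode cross-section: a filled ellipse (the
section) with an epidermis shell, a rind annulus holding vascular bundles
placed at seeded random angles on the mid-rind ellipse, and a pith with
bundles placed by seeded rejection sampling, all without overlap (bounded
attempts, failure raises). Each bundle is a disk (bundle interior) wrapped
in a sclerenchyma-sheath ring. Six tissue classes carry 11-channel mean
pseudospectra chosen to mimic real contrasts: parenchyma and epidermis
dominated by UV-induced blue emission, sheaths by strong visible-induced
emission, baseline channels near background. Pixel noise is additive
Gaussian with per-channel sd equal to 10% of the class-channel mean by
default, clipped to [0, 16383]; Gaussian noise was chosen over Poisson for
analytic tractability of the tests and the noise model is pluggable. An
optional cell-lattice texture darkens a lumen grid inside parenchyma to
emulate the wall/lumen bimodality of real tissue.

A series nests three variance levels, largest first: per-group spectral
multipliers (class × channel), an internode-level lognormal intensity
factor (sd 0.10 by default, emulating section-thickness variation), and
pixel noise. Section seeds derive from the base seed and the (group,
internode, section) indices, so series are bit-reproducible and
order-independent. The default test scale is 64–96 px sections (seconds
per series); the standard study shape is 4 groups × 5 internodes × 2
sections = 40 images. What the phantom does *not* emulate: optical
point-spread, shading residues, real cell-wall texture, and spatial
correlation of noise — so passing tests demonstrate the statistical
machinery, not robustness to acquisition artefacts.

Simulation-scale analyses use the ground-truth label map as ROI: a
101-px-diameter opening disk is larger than a 64-px phantom, so the
defaults for real macroscale images are meaningless at that size;
segmentation accuracy is verified separately on phantoms large enough for
the default radii.

## Rendering

Composites average U2r/BLr/GRr into red, U1g/U2g/BLg into green and
U1b/U2b into blue. The common 8-bit scale clips to [min, max], normalises
and applies a gamma exponent (defaults 0, 11000, 0.65 — gamma < 1 lifts low
intensities), rounding half-up. Per-image min/max and nearest-rank 1st/99th
percentiles are reported and the suggested common maximum is the largest
99th percentile; the suggestion is plumbing, the user override is the
contract. Zoom windows are picked at the ROI centroid and at the boundary
crossing of an eastward ray from the centroid (direction configurable — the
choice is a heuristic, nothing in the analysis depends on it), clamped
inside the image. Montages tile rows by group and columns by replicate
with 8-px padding, preserving each cell bit-exactly.

## Problem sizes in the test suite

Tests and the acceptance script run entirely on simulated series: 64–96 px
sections, 6–40 images per series, 500 replicates for null calibration and
100 for power. These sizes give Monte-Carlo error small enough for the
calibration bands checked (binomial sd ≈ 0.01 at 500 replicates) while the
whole suite stays in the minutes range on one CPU. The streaming design
itself is size-independent: the same code path handles 4000×4000-px images
at ~40 MB of resident data per image.

## Known limitations

- One-way ANOVA ignores the internode nesting (see above).
- Percentile rebinning loses information if the raw grid is too coarse for
  heavily concentrated scores; the refinement test bounds this by one
  raw-bin mass.
- The edge-overflow policy clamps rather than re-bins; inspect the overflow
  report if a series has extreme outlier scores.
- Group effects expressed purely as spatial rearrangement (same pooled
  pseudospectrum histogram, different geometry) are invisible to
  score-distribution features by design.
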