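# Methods

## The analysis model

`tonomap` reconstructs a six-region map of the mouse auditory cortex
(AAF, AI, AII, DA, DM, DP) from two independent measurement channels:

- **shape** comes from imaging: each region's responsive area is outlined
  on trial-averaged ΔF/F₀ maps and parameterized as a center-relative
  polar profile d(θ);
- **position** comes from histology-style stereotaxic measurements: each
  response focus's center is recorded as (RC, DV) — rostrocaudal mm from
  bregma (caudal positive) and dorsoventral mm from the dorsal tip of the
  rhinal fissure (dorsal positive).

The pipeline deliberately mirrors that separation: polar profiles are
averaged across animals *shape-wise* (by angle, center-relative), and the
averaged shapes are then placed at the per-band mean stereotaxic centers.
Averaging centers in pixel space instead would entangle optical and
histological coordinate frames that are registered only through the
stereotaxic system.

Ten (region, band) response areas exist: AAF, AI and AII each have a
low- (5 kHz) and high-frequency (30 kHz) area, DM has 30- and 60-kHz
areas, and the frequency-unorganized DA and DP respond to an FM
direction-reversal stimulus with one area each.

## Response processing

Per trial, ΔF/F₀ = mean over the response window of (F − F₀)/F₀, with F₀
the per-pixel mean of the five prestimulus baseline frames. The response
window defaults to the five frames after stimulus onset (the stimulus
lasts 500 ms ≈ 5 frames at 9.7 Hz; the window is configurable because the
analysis window is an acquisition choice, not a property of the method).
Trials (default 20) are averaged pixel-wise, then a 5×5 boxcar smooth is
applied, then Richardson–Lucy deconvolution. Order is configurable
(`smooth_before_deconvolve`); the default follows the processing order in
which the steps are conventionally described.

**Richardson–Lucy.** Light scatter through the parenchyma is modelled as
an isotropic Gaussian PSF whose "width" of 200 μm is interpreted as a
FWHM (the common imaging convention; a `width_is_fwhm` switch selects σ
instead). The iteration count is not dictated by the model; the default
is 10 and tests assert properties (peak preservation, FWHM reduction,
flux conservation) rather than a particular iterate. The multiplicative
update u ← u·K⊛(d/K⊛u) is applied directly, with K realised as scipy's
separable Gaussian filter in reflective-boundary mode. This choice is
load-bearing: reflective boundaries make a uniform image an exact fixed
point and conserve the image sum for interior-supported data, neither of
which holds under zero-padded convolution. ΔF/F₀ maps may be negative
while Richardson–Lucy requires nonnegative data, so maps with a negative
minimum are shifted up by it beforehand and shifted back afterwards; the
shift is recorded in the map's provenance.

## Outline extraction

The chain per response area: trim a window around the target region →
binarize at strictly greater than 60% of the window peak → keep the
largest connected component (8-connectivity, so diagonally abutting
pixels count as one island; ties broken by scan order) → increase pixel
density 50×50-fold by block replication → Sobel contour (horizontal
kernel [[1,2,1],[0,0,0],[−1,−2,−1]] and its transpose, combined as RMS;
any nonzero magnitude is a contour pixel, which is exact because the
input is binary and quantized) → centroid of contour pixels → polar
profile in 7200 bins of 0.05°, each bin the mean distance of its member
pixels, empty bins filled by circular linear interpolation.

Numerical conventions:

- Angle origin and sense: 0° along +RC (caudal), counterclockwise toward
  +DV (dorsal); declared in every serialized outline.
- Boundary handling for the boxcar and Sobel filters is reflective, so
  uniform images produce no spurious border responses.
- Non-star-shaped outlines are handled by the per-pixel binning itself
  (all contour pixels in a bin are averaged); no ray casting is involved.
- The centroid must lie inside the convex hull of the contour; otherwise
  the angular parameterization is ambiguous and the call fails loudly.

**Resolution.** Binarization happens on the native pixel grid and the
50× density increase replicates pixels, so the extracted contour is
quantized to the native grid: the worst per-angle deviation for a disk is
≈0.8 pixel pitch (≈16 μm at 20.4 μm/px), while the *centroid* averages
thousands of contour pixels and recovers centers to well under a pixel.
Tests assert exactly these bounds; sub-pixel contour accuracy claims
would require interpolating before binarization, which the method does
not do.

## Cross-animal averaging and map assembly

Profiles from n animals are averaged per angular bin; the per-bin SEM
(ddof = 1) is retained as the outline's dispersion (zero for n = 1). The
7200-sample average is downsampled to 72 samples by averaging each
5° block, which is what smooths the final outline. For each tonotopic
region, four intermediate centers are placed equidistantly on the
straight segment between the low- and high-frequency sites (tonotopic
gradients run roughly straight at this scale), and the outline morphs
linearly in proportion to distance along the segment. The six small
outlines are merged by geometric union; the union's exterior is then
resampled at 2.5° about the region centroid (≤144 vertices, outermost
intersection per ray), a smoothing step whose discretization is a few μm
at these outline sizes. Consecutive constituents must overlap; a disjoint
pair raises an error naming the gap so the caller can raise the number
of intermediates. DA and DP keep their single placed outline.

## Coronal projection

For each vertical gridline (2.0–4.0 mm posterior to bregma, 0.2-mm
steps) and region polygon, the intersection's minimum and maximum DV are
the ventral and dorsal boundary coordinates. Non-convex double crossings
report the outermost extent. Values are kept at full precision
internally; rounding (default two decimals) applies only to exported
tables, and crossings whose rounded width collapses to zero are printed
as absent — the atlas table contains no zero-width entries. The slice
measurement utility rotates a slice point and its rhinal-fissure
reference together by 15° (clockwise on the displayed slice) and reports
the signed difference of the rotated DV coordinates; because only the
relative coordinate is used, the measurement is invariant to the choice
of rotation center.

## The synthetic cohort

The generator emulates the study conditions: 128×168-px frames at
20.4 μm/px and 9.7 Hz, 20 trials per stimulus, 5 baseline + 5 response
frames, and ten response foci at the published mean injection-site
coordinates. Parameters and defaults:

| parameter | default | rationale |
|---|---|---|
| base contour radius | 0.15 mm | responsive areas are ~300 μm across |
| response amplitude A | 0.02 | flavoprotein ΔF/F₀ responses are typically 1–3% |
| rigid jitter SD | 0.1 mm | per-animal placement variability at the scale implied by published between-animal SEMs (≈SEM·√n) |
| pixel noise SD | 0.004 (= 0.2·A) | per pixel per frame, ΔF/F₀ units |
| baseline F_b | 1000 counts | arbitrary; ΔF/F₀ cancels it |
| injection measurement SD | 0.2 mm | gives n = 5 SEMs in the published 0.02–0.17-mm range |
| RC snap step | 0.02 mm | atlas plates discretize the rostrocaudal judgement |

The focus profile is a raised cosine G(r) = (1 + cos(π·r/(s·R)))/2 with
s = π/arccos(0.2), i.e. G = 1 at the center, **0.6 exactly at the base
contour R**, and 0 at ≈2.29·R. Anchoring the 60% level at the contour
makes the base contour directly the ground-truth responsive-area outline
that the >60% threshold recovers, and reproduces the geometry in which
consecutive constituent outlines overlap so the six-outline merge is
well-posed; a profile reaching zero at the contour would shrink the
extracted areas to ~0.44·R and leave them disjoint. Jitter is a rigid
per-animal translation (all foci move together), with optional
independent per-focus jitter; both are deterministic functions of
(seed, animal index), and noise streams additionally key on stimulus and
trial, so identical seeds reproduce cohorts bit-for-bit.

What the generator does **not** emulate: vascular and hemodynamic
artifacts, the 75° head-rotation optics, anisotropic or non-Gaussian
scatter, time-varying response kernels, and histological distortions
(shrinkage, slice rotation). Passing tests therefore demonstrate that
the analysis recovers known geometry under the stated statistical
structure, not that it is robust to every artifact of real recordings.

## Pipeline targeting

Trimming around a target region is a manual step in practice. The
pipeline automates it by detecting local response maxima per stimulus
map and matching them to the nominal band centers by minimum total
assignment distance: because the rigid jitter moves the whole focus
constellation together, constellation matching tolerates displacements
far larger than the inter-focus spacing (≥0.52 mm within a stimulus),
where a fixed window around the nominal center could capture a
neighbouring band's core. Unmatched bands fall back to the brightest
pixel within 0.45 mm of the nominal center. The trim window (±0.30 mm)
is then centered on the located peak.

## Problem sizes

The default end-to-end analysis uses 5 animals × 4 stimuli × 20 trials
of 10-frame 128×168 stacks (≈30 s on one CPU); end-to-end accuracy tests
use single synthetic disks at 2.55–20.4 μm/px, 100 random 32×32 masks
for the Sobel cross-check, and 50 random star polygons against a 1-μm
rasterization oracle for the gridline projection. The small packaged
fixture cohort (2 animals, 3 trials, half resolution) regenerates
bit-identically from its seed.

## Known limitations

- Contour localization is bounded by the native pixel grid (see
  Resolution above); the 50× upsampling defines the contour coordinate
  system but adds no information.
- The intermediate-outline bridge assumes a straight tonotopic axis; a
  curved gradient would need curved center placement.
- Whole-region polygons depend on the union-resampling step only through
  a few-μm discretization, but regions are not guaranteed star-shaped
  about their centroid for arbitrary inputs; the outermost-intersection
  rule then reports the outer envelope.
- The boundary table inherits the surface map's axis conventions; it
  does not model cortical curvature or layer depth on real slices.
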