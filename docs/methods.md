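# Methods

## Focal correction

The in-focus surface of a curved sample is modeled as an explicit 2D
manifold z_f(x, y) through the stack. Evidence for its position comes from
the DAPI channel only: nuclear borders are the sharpest features in
epithelial imagery, and their Sobel-gradient magnitude peaks at the slice
where the border is best focused. Per pixel, M(x, y) is the maximum of the
gradient magnitude along z and z_m(x, y) its argmax (ties resolve to the
lowest slice, for determinism). Because borders cover only a small fraction
of the field, z_m is noise-dominated elsewhere; weights below
0.1 × prc99(M) are therefore zeroed before a weighted least-squares fit of a
bivariate polynomial of **total degree ≤ 5** (21 terms) on coordinates
normalized to [−1, 1] per axis. The normalization keeps the Vandermonde
system well conditioned at any frame size; "order 5" is read as a total
degree bound rather than per-axis degree (per-axis can be requested through
the `degree` machinery but is not the default) because 21 terms already
track realistic sample unevenness without ringing. The fitted surface is
evaluated unclamped; clamping to [0, z_count−1] happens only at
interpolation. Each channel is then linearly interpolated between the two
slices bracketing z_f. Surface values within 1e−9 of an integer are snapped
to it so that a flat integer manifold reproduces its slice bit-exactly
despite least-squares roundoff.

Degenerate inputs: a weight mask with fewer positive pixels than
coefficients, or one that concentrates on a line (rank-deficient design),
raises instead of returning a silently extrapolated surface.

All percentiles in the package use numpy's linear-interpolation convention;
the thresholds above depend on it, so it is fixed and stated once here.

## Segmentation

Two marker-controlled watershed transforms, both 4-connected, with every
pixel receiving a label (scikit-image's queue-based watershed assigns ridge
pixels to the region that reaches them first at their gray level).

*Stage 1 — nuclei.* The in-focus DAPI image is smoothed (Gaussian σ = 3 px),
and a soft background — erosion by a disk of radius 9 px, dilation by
18 px, Gaussian smoothing with σ = 9 px — is subtracted and clipped at
zero, removing every object smaller than the 9 px radius. The outer
smoothing kernel's scale is read as σ = r_n (the plausible alternatives,
radius-r_n uniform kernels, differ negligibly after the clip). Remaining
intensity unevenness is flattened by dividing by a degree-2 polynomial
surface fitted to the image *using the image itself as weight* (so only
nuclei drive the fit); the surface is floored at 1e−6 of its maximum
before division, since the ratio is only meaningful where nuclear signal
exists. Nuclear seed markers are the h-maxima of the upper half of the
flattened image (values below the median are clipped off) with
h = 0.1 × prc99.9; `skimage.morphology.h_maxima` returns precisely the
binary "maxima of height ≥ h" marker mask required downstream. The
extranuclear marker is the sub-median region eroded by a 2 px disk. The
watershed floods the DAPI gradient magnitude.

*Stage 2 — cells.* Nuclei become cell seeds (keeping their labels). The
relief is the sum of the two protein-channel gradient magnitudes with a
2 px dilated kill zone around nuclear space zeroed, so nuclear borders do
not imitate cell borders. Acellular space is seeded by the opening
(erosion then dilation by a disk of radius d_avg) of the region farther
than 2·d_avg from any nucleus, where d_avg is the mode of the
Gaussian-regularized histogram (1 px bins, kernel sd = 2 bins — the
regularization scale is not prescribed anywhere authoritative, so it is a
package choice, exposed as a parameter) of the distance transform of the
nuclear mask. On a confluent sheet this marker is empty and all pixels are
assigned to cells.

Compartments: the nucleus of cell *l* is the stage-1 region with the same
label, the cytoplasm is the rest of its stage-2 cell; per-cell means of
both protein channels in both compartments go into a tidy table. A cell
whose nucleus vanished (not observed in practice) is dropped with a
warning rather than poisoning the table.

Structuring-element sizes are in pixels exactly as tuned for
~0.5–0.6 µm/px imagery and are exposed in `PipelineConfig`; they are not
rescaled by pixel size automatically.

## Edge profiles and interval fractions

Profiles are unweighted column means (columns are not weighted by cell
coverage — the simplest reading, and the one consistent with profiling a
rotated rectangular ROI) resampled into half-open 5 µm bins
[5k, 5(k+1)). The interval fraction uses the proximal band 5–30 µm and
distal band 50–80 µm; the first 5 µm (tissue entering view across an
irregular border) and the 30–50 µm transition are excluded. IF is a
*fraction*, not a ratio, to avoid the unstable small-denominator regime;
it is invariant to global intensity scaling and to profile normalization.
IF > 0.5 indicates proximal accumulation — the orientation follows
directly from the defining formula, since the proximal mean appears in the
numerator. Profile normalization divides by the profile's mean
over 0–80 µm. Aggregation across samples reports per-bin mean, sample SD
(n − 1) and SEM = SD/√n, with SD undefined below two samples — the n − 1
convention is chosen to match SEM's sampling-theory meaning.

Rotation to align the cut vertically is bilinear about the frame center;
when a border polyline is supplied the angle is the polyline's principal
(SVD) direction and the border column is the mean rotated x. Destruction
area closes the cut polyline against the reversed border polyline and
applies the shoelace formula; crossing polylines are rejected.

## Colocalization

Correlations are Pearson and Spearman (mean ranks on ties). Significance
of image correlations uses tile randomization: the image pair is cropped
to 8×8 px tile multiples, the tiles of one image are permuted n_perm times
(default 200; the permutation count is a package choice), and
p = (1 + #{|r_null| ≥ |r_obs|}) / (n_perm + 1), two-sided via |r| and
never exactly zero. Fewer than 19 permutations, or a single tile, is
rejected.

Cooccurrence thresholds follow the Costes stopping rule along a
*percentile-pairing* curve: Th_A(q) and Th_B(q) are the same quantile q of
each image, and q walks downward from 99.9 in 0.1 steps (both
configurable) until the Pearson correlation of the outside region
(A ≤ Th_A or B ≤ Th_B) drops to ≤ 0. Pairing by quantile rather than by an
orthogonal regression tolerates nonlinear relations between channels. If
the outside correlation never reaches zero there is no separable
colocalized population; the thresholds fall back to the curve minimum with
a warning. Manders M1 and M2 are the fractions of each channel's total
intensity inside the cooccurrence mask.

Compartmental analysis: nucfr = nuc/(nuc + cyt) per cell and channel; the
six compartment-mean pairings (within-compartment between channels,
cross-compartment, and within-channel across compartments) plus
cytoplasmic-A vs nucfr-B each get PCC, SRCC, analytic two-sided p, and an
orthogonal regression computed as the first principal axis of the
*standardized* pair, de-standardized to slope sign(r)·sd(y)/sd(x) through
the means. Cells with high channel-B nuclear fraction (HNF,
nucfr > 0.5 by default — the cutoff is a package choice, exposed as a
parameter) are compared against the rest on cytoplasmic channel A with the
normality-gated unpaired test, provided at least 5 cells fall in each
group. Compartment-restricted pixel correlations pool all cells' nuclei
(or cytoplasms) into one mask.

## Statistics

Every sample is tested with Shapiro–Wilk at α = 0.05 (scipy's
implementation, valid for 3 ≤ n ≤ 5000). Descriptions always include mean,
sample SD and the t-based 95% CI of the mean; non-normal samples add
median, interquartile interval, and a binomial order-statistic 95% CI of
the median (interval (x₍ₘ₎, x₍ₙ₊₁₋ₘ₎) with m = Binom⁻¹(0.025; n, ½),
guaranteed ≥ 95% coverage for continuous data). Comparisons gate on the
relevant quantity — the sample itself (one-sample), the pairwise
differences (paired), or both groups (unpaired) — and use Student's t
(one-sample, paired), Welch's t (unpaired), Wilcoxon signed-rank
(one-sample, paired) or the rank-sum/Mann–Whitney test (unpaired), all
two-sided. An explicit `branch=` override lets the analyst force either
branch.

Effect sizes: one-sample d = (mean − μ₀)/SD; paired d = mean(diff)/SD(diff)
and d′ = mean(diff)/pooled SD of the two samples (several d′ conventions
circulate; the pooled-SD standardizer is the natural pairing-insensitive
companion to d and is the package's documented choice); unpaired d uses
the pooled SD and d′ the
average-variance standardizer √((s₁² + s₂²)/2). Probability of superiority
is U/(n₁n₂) with tie halving. d is positive when the first argument's
location exceeds the second's. Degenerate inputs (constant samples,
all-zero differences) return flagged results with p = 1 when the locations
agree exactly, rather than NaN.

## The phantom generator

The generator emulates the study geometry at desk scale: 128 × 128 px
frames, 21 slices, 30 cells (configurable). Nuclei are disks of radius
6 px placed by best-candidate rejection sampling (pairwise separation
≥ 2r + 2 px, margin ≥ r) followed by Lloyd relaxation toward a
contact-inhibited lattice — confluent monolayers have near-uniform nearest-
neighbour spacing, and the void-marker stage of the segmentation assumes
that regularity. Cytoplasms are the Voronoi regions of the nuclei
(optionally clipped to a sheet mask), so the sheet is confluent without
modeling membranes. Per-cell protein means are bivariate normal
(base 100, SD 20) with a configurable Pearson correlation; nucleoplasm
carries 0.25× the cytoplasmic level (nuclear exclusion); DAPI is 200 in
nuclei over a background of 2.

Defocus is modeled as a per-pixel Gaussian blur of
sd = 0.75 px × |k − z_f(x, y)| (capped at 6 px), realized by blending a
bank of pre-blurred scenes at 0.5 px sd spacing — cheap, and monotone
sharpness in |k − z_f| is the only property focal correction relies on.
Noise defaults to the photon-limited regime: Poisson resampling at 1 count
per intensity unit — SNR = √100 = 10 at the cytoplasmic base intensity —
plus Gaussian read noise of SD 2. Signal-dependent shot noise matters
here: background regions then carry almost no gradient energy, which is
the regime the gradient-threshold weighting (0.1·prc99) was designed for.
A spatially uniform additive noise floor of comparable magnitude would
instead flood the weight mask with spurious argmax pixels — real confocal
data is shot-noise-limited, so the generator is too.

What the phantom does **not** emulate: optical PSF physics and spherical
aberration, brightfield, folded tissue (multi-valued focus surfaces),
mitotic or overlapping nuclei, intra-cell intensity texture, and
inter-channel bleed-through. Passing tests therefore demonstrate the
pipeline's correctness under ideal monolayer geometry and photon-limited
noise, not robustness to every acquisition pathology.

## Numerical choices and degenerate inputs

- Percentiles: numpy linear interpolation, everywhere.
- Argmax ties: lowest slice. On perfectly symmetric synthetic stacks this
  biases the argmax map downward (slices k ± m blur identically); the
  phantom's randomly curved default surface avoids exact ties.
- Watershed connectivity: 4-connected; all pixels labeled.
- F_nuc floor: 1e−6 × max; h-maxima on an all-flat image yields no
  markers and a warned, nucleus-free result instead of a crash.
- Interpolation snap tolerance: 1e−9 slices.
- Randomization p-values use the +1 convention.
- JSON/CSV outputs are written deterministically (sorted keys, fixed float
  format); rerunning a pipeline with the same config and seed reproduces
  numeric outputs byte-for-byte, and every output bundle records the
  config hash, parameters and library versions in its run log.

## Problem sizes

Tests and the acceptance script run phantoms at 128 × 128 × 21 with 30
cells, correlation fixtures at 256², calibration loops at 500 runs
(tile shuffle) and 1000 replicates (statistical branches at n = 25) — sizes
at which every sampling-error bound asserted in the tests is comfortably
resolvable.
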