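# Methods

This note documents the models and procedures implemented in `cyclicproc`,
the parameters that matter, the design choices made where the procedure was
genuinely open, and what the synthetic fixtures do and do not emulate.

## Registration

Each staining round is mapped onto the reference round (default: round 1,
the first stained round) by a planar affine transform estimated between the
two rounds' DAPI images. The estimator is the classic keypoint pipeline:
ORB invariant keypoints (800 per image), Hamming-matched descriptors with
cross-checking, and a RANSAC affine fit (inlier tolerance 2 px, 2000 trials,
fixed internal seed for determinism), followed by a least-squares refit on
the inlier set. Because keypoint localization is only pixel-accurate, a
final sub-pixel translation correction is estimated by upsampled phase
correlation (factor 20) between the reference and the warped moving image.
Any invariant detector satisfying the recovery property would do; ORB is
used because it is fast and dependency-free.

Failure is explicit: fewer than `min_matches` (default 10) consistent
correspondences, or a post-fit RMS residual above 5 px, raises a
registration error naming the round. Within a round, every channel receives
the identical transform. Warping uses bilinear interpolation with zero fill
outside the field; zero-filled borders bias border-cell intensities, so
downstream QC should drop cells touching the border (the transforms are
serialized so coverage can be reconstructed).

On synthetic nuclei fields, planted perturbations within scale 0.98–1.02,
rotation ≤ 5°, shift ≤ 20 px are recovered with mean displacement below
0.5 px over the field (verified in the test suite for three random draws).

## Autofluorescence subtraction

Quenching leaves residual tissue autofluorescence (AF), strongest in the
AF488/AF555/AF647 channels, negligible in AF750. Blank (unstained)
acquisitions of each channel estimate the AF field. Camera counts scale
linearly with integration time, so a blank at exposure `e_b` predicts the AF
of a marker image at exposure `e_m` after multiplication by `e_m/e_b`.

- **Baseline**: one blank per channel is exposure-scaled and subtracted from
  all rounds. The recommended blank is collected after 3–4 quench rounds,
  near the AF minimum, which avoids over-subtraction elsewhere; a warning is
  issued when the round-0 (pre-quench, brighter) blank is used as baseline.
- **Scaled**: AF at round r is modelled as the linear interpolation in round
  index between an early blank (round `r_e`) and a late blank (round `r_l`):
  `AF(r) = (1−w)·B_e + w·B_l`, `w = (r−r_e)/(r_l−r_e)` clamped to [0, 1].
  Clamping rather than extrapolation is deliberate: extrapolating a fitted
  decline beyond the observed blanks risks over-subtraction.

Negative differences are clamped to zero before the cast back to 16-bit
(a flag preserves the signed float difference for diagnostics). DAPI and
AF750 pass through unchanged by default; the corrected channel set is
configurable.

## Segmentation

Nuclei are segmented from the pixelwise **maximum** projection of all
rounds' registered DAPI images — maximum rather than mean, so nuclei of
cells that detach in later rounds remain segmentable. Steps:

1. white top-hat with a disk of radius 15 px (≈ the expected nuclear
   radius at 0.325 µm/px);
2. foreground by Otsu's threshold on the smoothed top-hat;
3. seeds = local maxima of the Euclidean distance transform of the
   foreground, minimum separation 5 px (distance-transform maxima are robust
   to the intensity plateaus of in-focus nuclei, where raw intensity maxima
   fragment under shot noise);
4. relief = Prewitt gradient magnitude of the projection; seeded watershed
   restricted to the foreground;
5. objects above their class's size cap are trimmed to the pixels nearest
   the seed centroid. Caps default to 1200 px² for cytokeratin-positive
   (epithelial) cells and 600 px² for others; seed-level positivity, when
   used, is the mean marker intensity in a small disk around the seed
   against a threshold — the size-cap *rule* is principled, the numbers are
   conventions and are configurable.

Whole cells: membrane(Ecad)-positive nuclei seed a watershed on the membrane
intensity image, so basin divides fall on the bright membrane ridge between
adjacent cells; a background seed placed in low-membrane territory beyond
`max_cell_radius_px` (default 20) bounds each cell. Membrane-negative nuclei
are expanded 5 px (1.6 µm), the average immune-cell cytoplasm width.
Membrane negativity defaults to Otsu on the mean membrane intensity in the
5 px ring, with manual override. Cytoplasm = cell − nucleus, possibly empty.

Label expansion uses exact Euclidean distances; contested pixels go to the
nearest label, distance ties to the smaller label id (deterministic, and
verified exactly against a brute-force oracle).

On synthetic fields of non-touching soft-edged nuclei with Poisson noise,
object-level F1 at IoU ≥ 0.5 is ≥ 0.95 with count error ≤ 2%.

External deep-learning segmenters are supported by importing their label
TIFFs; the documented Cellpose preset (cells: diameter 30 px,
flow_threshold 0.6, min_size 113; nuclei: diameter 30, flow_threshold 0,
min_size 28) is configuration only — running Cellpose is out of scope.

## QC metrics

**SBR.** `([mean of pixels above threshold] − [mean background]) / [mean
background]`, where background pixels lie at or below the threshold *and*
strictly more than 30 px (10 µm, Euclidean — a disk, not a square dilation)
from any foreground pixel, excluding manually masked artifacts. "Positive"
is strictly greater-than; on integer data ties matter, so this is
documented. A marker with no positive pixel is flagged
`negative_in_tissue` and not analyzed. The quantile variant reports the 4th
and 99.5th percentiles as the dynamic range and `(q995 − q4)/q4` as an
SBR estimate.

**Tissue retention.** Per round, a Li minimum-cross-entropy threshold
(initial guess: mean intensity) is applied to DAPI; a cell is retained if
its mean DAPI exceeds the threshold, and retention is the retained fraction
of the reference-round population (never reported above 1). The threshold is
computed per round (exposure varies across rounds) and, preferably, on DAPI
*image pixels* rather than per-cell means: image pixels always contain the
slide-background mode, so the threshold splits nuclei from background even
in rounds without any loss, where the per-cell distribution is unimodal and
minimum-cross-entropy thresholding is unstable. The denominator (reference
positives) is configurable.

## Normalization

**Exclusivity score.** Markers expressed in mutually exclusive cell
populations form L-shaped joint distributions. The implemented R-value is
the minor/major singular-value ratio σ₂/σ₁ of the n×2 standardized
(mean 0, sd 1) pair matrix, which equals √((1−r)/(1+r)) for a correlation-r
bivariate pair. Strongly co-expressed pairs (|r| large) score near 0;
realistic heavy-tailed exclusive pairs (moderate negative r) score ≈ 0.7.
Caveat: a pair of *independent* markers (r ≈ 0) also scores near 1, so the
score separates exclusive from co-expressed pairs but not from independent
ones; in practice marker panels track cell lineages and truly independent
pairs are uncommon. Cut-offs: per core 0.5 (fallback 0.2 when no pair
qualifies), global 0.66 (fallback 0.5); markers without any partner at the
fallback are flagged unnormalizable.

**RESTORE threshold.** For each exclusive partner, the partner-positive
subpopulation (top quartile of partner intensity — by exclusivity these
cells contain only background for the marker) contributes a candidate
threshold, the 99.5th percentile of the marker there; candidates from
subpopulations under 20 cells are skipped with a warning. The final
threshold is the median candidate. Both quantiles are configurable.

**RESTORE scale.** Cells at or below threshold receive a seeded uniform
random value in (10⁻⁶, 0.02); cells above are mapped affinely from
[threshold, max] to [0.02, 1], so the brightest cell is exactly 1 and order
is preserved. The seed is a required input for reproducibility.

**Reverse-compartment threshold.** For a marker with known localization, the
opposite compartment carries only background; the threshold is its third
quartile (e.g. Q3 of cytoplasmic signal for a nuclear marker).

**Transforms and scalers.** log2 uses a +1 pseudo-count; arcsinh uses
cofactor 5 (the cytometry convention). Scalers delegate to scikit-learn
(standard, min-max, max-abs, robust, quantile, power).

**ComBat.** Per feature, data are standardized by the grand mean and pooled
within-batch variance of the *training* cells; per batch, location (γ) and
scale (δ) estimates are shrunk by parametric empirical Bayes (normal prior
on γ, inverse-gamma prior on δ², priors moment-matched across features,
fixed-point iteration to 10⁻⁴) and the adjustment is applied batch-wise to
all cells. Training modes: `all` (every cell), `same` (one control core
present in every batch), `sampled` (cells pooled from several control
cores). The implementation is in-house because fitting on a training subset
and applying to the full table is required; it is cross-checked against the
scanpy ComBat implementation in the test suite. In the no-shrinkage limit
the training cells' per-batch means and variances are equalized exactly.

A practical note encoded in the evaluation defaults: location/scale
correction estimated from the *moments* of heavy-tailed raw intensities is
noisy (a few-percent scale error misaligns the narrow background peak
between batches), so the batch-correction evaluation operates on
log2-transformed intensities, where moments are stable. Raw-scale ComBat
("without log2 transformation") remains available as a preset.

**Regress-out** subtracts the per-batch mean and restores the grand mean,
feature-wise; variances are untouched.

## Batch evaluation

**kBET.** On an exact Euclidean k-NN graph (ties broken by cell index), each
tested neighborhood is an anchor cell plus its k neighbors (k+1 cells).
Observed batch counts are compared with expected counts (global batch
proportions × (k+1)) by a Pearson chi-squared statistic with B−1 degrees of
freedom, no continuity correction; the rejection rate is the fraction of
100 (default) seeded random neighborhoods with p < α (default 0.05). The
default k is a quarter of the mean batch size, capped at n−1. Perfectly
mixed batches reject at ≈ α; fully separated batches reject at 1.

**Stratified sampling** draws exactly 600 cells (default) per (core, batch)
group without replacement, seeded; deficient groups are an error naming the
group. **Clustering** is Leiden (RB-configuration, resolution 0.6, seeded)
on the pooled normalized table, so cluster labels are shared across
replicates by construction — no post-hoc label matching. **Cluster
composition correlation** is the Pearson r between the per-cluster cell
fraction vectors of two replicates within one core; 3 cores × 3 replicate
pairs yield 9 values.

## Synthetic fixtures

The image generator places non-overlapping soft-edged (sigmoid-profile)
nuclei, adds per-round AF (a diffuse smooth field plus bright curvilinear
fibers, 2–10× the signal, emulating the bright tissue structures that
dominate real AF) scaled by a per-round multiplier v(r) — default:
piecewise-linear decline to a minimum at rounds 3–4, rise afterwards, the
dynamic observed for quenched tissue — plus Poisson shot noise and Gaussian
read noise (sd 2), per-round affine jitter (≤ 8 px, ≤ 2°), and a
non-increasing retention schedule that deletes cells' DAPI and signal in
later rounds. Blank acquisitions are emitted at configurable rounds.

The table generator draws 1000 cells per (core, batch) for 3 cores ×
3 batches. Markers come in lineage groups (epithelial CK19/Ecad vs
immune-stromal CD45/Vim, 50/50); a cell expresses its own lineage's markers
— co-expressed through a shared per-cell lognormal staining factor (residual
log-sd 0.25) — and background lognormal(log 50, 0.3) otherwise. Signal is
lognormal(log 800, 0.8): the heavy tail matches the decades-wide dynamic
range of immunofluorescence and is what places exclusive pairs above and
co-expressed pairs below the selection cut-offs. Batch effects are a
per-batch gain (1.0 / 1.6 / 0.7) and offset (0 / 20 / 10). The planted
background threshold per marker is the analytic 99.5th percentile of the
background lognormal.

What the fixtures do **not** emulate: optics (PSF, defocus, vignetting),
tissue texture and autofluorescence spectra, segmentation-error propagation
into the cell table, spatial correlation of cell types, marker-specific
staining kinetics, and cross-channel bleed-through. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not performance on real tissue.

## Problem sizes and numerics

Test and acceptance workloads are sized for a single CPU: 256²–512² rasters,
50–300 cells per scene, 9 000-cell tables, k-NN graphs on 5 400 cells. Exact
(brute-force-verified) components — label expansion, SBR gap masking, mean
intensity, k-NN — are checked on ≤ 64×64 rasters / ≤ 200 cells where
exhaustive oracles are cheap. Stochastic checks fix every seed. Degenerate
inputs (constant images, empty compartments, single batches, zero-variance
features) raise explicit errors or warnings rather than propagating NaNs;
the one deliberate NaN is the missing-compartment intensity, which is kept
missing (never zero) to avoid biasing background statistics.
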