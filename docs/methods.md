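# Methods

`ishquant` quantifies gene copy-number status and tumour heterogeneity from
bright-field images of dual-colour in-situ hybridization (DISH) assays,
where a gene probe deposits near-black silver dots and a chromosome
enumeration probe (CEP) deposits red dots. The pipeline is deliberately
nucleus-free: it never segments cells, only detects, classifies and counts
dot signals, so it stays cheap at whole-slide scale.

## Image handling

Single tissue cores are resized by bicubic interpolation to a fixed
4096 x 4096 working frame, so every pixel-unit parameter downstream
(radii, neighbourhood sizes) has a fixed meaning. Whole slides keep their
native resolution and are processed as 4096 x 4096 tiles (default 64 px
overlap); per-tile detections are shifted to slide coordinates and
deduplicated by greedy non-maximum suppression (strength-descending, ties
by (x, y)), which makes the merge independent of tile order. Scanner
auto-corrections (white balance, contrast) are assumed already applied;
gray-world white balance and a percentile contrast stretch exist but are
off by default, to avoid double-correcting.

The tissue mask is a threshold on luminance (< 0.94) or saturation
(> 0.06) with small-object removal and hole filling — tissue is anything
not near-white. It is computed with integer arithmetic because it runs on
full-frame rasters.

## Signal detection

Detection is a two-stage gradient-accumulator circular Hough transform,
the classic construction for small-circle finding:

1. A scalar contrast channel is built in which target dots are bright:
   inverted luminance (catches black and red dots), red chroma
   `max(R - (G+B)/2, 0)` (red dots only), or both. The default runs one
   pass per channel and merges the deduplicated union, because black and
   red dots have different contrast signatures.
2. The channel is smoothed (sigma 1.0) and every pixel whose gradient
   magnitude exceeds `edge_threshold` (default 0.04 on the [0, 1] channel)
   casts one vote per candidate radius r in [radius_min, radius_max]
   (default [3, 12] px, about 0.3-1.3 um at a typical 0.11 um/px after
   resizing) at the position one radius uphill along its gradient — i.e.
   at the presumptive circle centre.
3. Votes are weighted 1/(2 pi r), so a complete circle of any radius in
   range deposits about the same total mass at its centre. The
   accumulator is therefore scale-free, and `sensitivity` maps directly to
   a peak threshold of `1 - sensitivity` (default 0.82). A second
   accumulator collects radius-weighted votes; their ratio at a peak is
   the radius estimate.
4. Peaks are strict local maxima (deterministic plateau tie-break), then
   non-maximum suppressed at `min_separation` (default 4.5 px = 1.5 x
   radius_min).

Lowering `sensitivity` provably never increases the detection count: the
threshold removes a suffix of the strength ordering, and greedy NMS
decisions depend only on stronger points. Gradients and vote scatter are
computed in row blocks and accumulator smoothing is chunked, so a
single-pass run on a 16,384^2 slide peaks below ~4 GB.

On planted synthetic cores (1,000-5,000 dot signals) the detector's
precision and recall at a 2-px matching radius are both ~1.00; the tuned
defaults are nevertheless config-exposed because real staining and
digitization shift the optimum.

## Signal classification

Each detection is summarized by 14 appearance features from the disk of
its estimated radius and the surrounding 2x annulus: RGB means and SDs,
CIELAB a*/b* chroma of the mean colour, radius, ring-minus-disk luminance
contrast, disk luminance mean and SD, a mean absolute luminance-step
gradient proxy, and mean saturation. Hue and darkness carry almost all of
the class signal (black gene dots, red CEP dots, dark-red colocalized
mixed dots, faint brown debris, pale blue diffuse stains), so a small
dense feature vector plus an RBF-kernel SVM (one-vs-one, inverse-frequency
class weights) is the right size of model. C is searched over
{0.1, 1, 10, 100} and gamma over the median heuristic times 2^-4..2^2, by
stratified 5-fold cross-validation; ties resolve to smaller C. Label
confidence is a softmax-normalized decision margin. A persisted model
carries its feature layout and refuses to classify if it does not match
the extractor.

The label vocabulary is probe-agnostic (GENE/CEP), so the same code path
serves deletion assays (e.g. a tumour-suppressor probe against its
chromosome's CEP) and amplification assays.

## Copy-number scoring

The global ratio of a region is (all gene signals) / (all CEP signals);
debris and stain detections never count. A colocalized mixed signal
contains one dot of each channel, so the default `count_both` policy adds
one to both counts; `exclude` drops mixed signals and exists for
sensitivity analysis. Deletion is called at ratio <= 0.60 (boundary
inclusive), amplification at >= 2.0.

`roc_analysis` supports threshold tuning against a manual reference:
trapezoidal AUC (identical to the Mann-Whitney rank statistic — asserted
to 1e-12 against a brute-force pair enumeration), 95% CI by percentile
bootstrap over 1,000 case-resampled replicates (replicates that lose a
class are redrawn), and an operating point by Youden's J (the equal-cost
slope criterion) or closest-to-(0,1). The percentile interval is an
asymptotic construction: measured coverage of the 95% CI is ~95% at 400
cases per class but ~92% at 60 per class; the calibration benchmark uses
the former so it tests the method where its guarantee applies.

## Heterogeneity statistics

The global ratio hides spatial structure; heterogeneity is read from the
distribution of local ratios. For one core:

* draw `n_random` (default 300) points uniformly over the tissue mask and
  snap each to its nearest *not-yet-used* CEP signal ("without
  replacement" — no CEP anchors two neighbourhoods; if there are at most
  `n_random` CEPs, all become anchors);
* around each anchor, count gene and CEP signals within `radius` (default
  60 px, wide enough to include at least one adjacent cell at the
  generator's cell density); the randomized local ratio (RLR) is
  gene/CEP, the randomized local density (RLD) is gene+CEP. The
  KD-tree counting is asserted to equal an exhaustive O(n m) oracle
  exactly;
* summarize each distribution by mean, median and SEM (sample SD, n-1)
  — a 6-D core feature vector.

Cohorts of cores are z-scored per feature (the six features have
incommensurate scales; constant columns are dropped with a warning),
embedded by PCA onto two components with deterministic sign convention,
and clustered by full-covariance Gaussian mixtures, k = 1..5, minimum AIC
(2p - 2 log L, p = 6k - 1 in 2-D), EM with k-means init and 10 seeded
restarts. EM with many restarts reliably discovers degenerate "sliver"
components — a few near-collinear points with near-singular covariance —
whose likelihood tricks AIC into overselecting k, so component covariances
are floored at `reg_fraction` (default 0.05) of the data's mean
per-dimension variance; with the floor, 3 well-separated planted clusters
are selected in ~100% of draws and a single Gaussian yields k = 1 in ~95%.

The reference component is the one whose member cores have the lowest mean
RLR (deletion = low gene:CEP ratio); each core's heterogeneity grade is
its Mahalanobis distance to that component's mean under that component's
own covariance. Robustness ellipses rerun the anchor sampling with
n_random cycling 201..300 over 100 repetitions (seed base + i), project
every repetition with the cohort's frozen standardization and loadings,
and draw the 95% chi-square(2) confidence ellipse of the repetition cloud
(the cloud's ellipse, not the mean's CI — repetition scatter is the
quantity of interest, and a mean-CI would shrink to invisibility at
100 reps).

## Synthetic data

The generator is the package's study bench: cells are placed by a
hard-core process (min spacing 42 px) inside a circular tissue region
(radius 560 px) on a pale textured hematoxylin-like background; each cell
emits Binomial(copies, 1 - loss) dots per channel, jittered within the
cell radius with a minimum inter-dot distance so neighbouring dots remain
resolvable; a fraction of gene/CEP pairs colocalize into mixed dots
(rendered as overlapping black+red, offset 1.5 px — well under the NMS
radius, so they detect as one signal); brown debris dots and large
diffuse bluish stains are added at per-area rates. Defaults (330 cells,
~2,300 debris/stain points) put ~3,400 plantable signals per core with
~30% of detections classified GENE or CEP, the regime typical of one
stained core. Sectioning signal loss (default 0.15) hits both channels
equally, so the expected global ratio — mean planted gene copies per cell
over `cep_copies`, an exact conditional expectation given cell placement —
is invariant to it; unequal loss can be configured for robustness
experiments.

Six prototypes span the genotype/heterogeneity space: homozygous deletion
(gene-0 centre with a thin 2-copy benign rim, as residual normal
epithelium survives real sections), hemizygous deletion (1 copy),
non-deletion (2 copies), cellular heterogeneity with homogeneous genotype
(2 copies, clustered cell density), cellular heterogeneity with
heterogeneous genotype (deleted blob in a normal surround, clustered
density) and intra-tumour heterogeneity (half-plane 2 vs 0 copies). Whole
slides are mosaics of core tiles (default 4 x 4 = 16,384^2 — a desk-scale
stand-in; the tiling logic is what matters, not the canvas size).

What the generator does **not** emulate: nuclear texture and chromatin
detail, stain deconvolution artefacts, focus drift, tissue folds, or
out-of-range dot sizes. The synthetic palette makes the five classes
separable essentially by construction, so the ~100% classifier CV
accuracy and near-perfect detection recovery bound what the *pipeline
machinery* can do, and validate the statistics end-to-end against planted
truth — they are not claims about performance on real slides, where the
classifier must be retrained on expert annotations and the Hough
parameters retuned per staining/digitization protocol.

## Benchmark problem sizes

The reproduction script (`scripts/acceptance.py`) and the acceptance test
battery use: 20 full-pipeline cores (cycling non-deletion / hemizygous /
homozygous; the first 10 also grade detection), 100 random configurations
for the RLR/RLD oracle, 10 twelve-core cohorts for the heterogeneity
orderings, 100 draws of 71 points for mixture-model selection (plus 20
single-Gaussian controls, reported as the modal k), 50 score/label sets
for the AUC oracle plus a 2,000-sample null and 100 coverage runs, and
one 16,384^2 half-plane mosaic for the tiled-vs-single-pass comparison.

## Known limitations

* Dot radii outside [3, 12] px at working scale are invisible to the
  default detector; cell stains are found only insofar as debris-like
  detections land on them.
* The anchor procedure needs at least one CEP signal; cores with a
  failed CEP channel produce an undefined ratio and no status call
  rather than a guess.
* AIC's covariance floor trades a small bias in fitted component
  covariances (+5% of data variance per dimension) for selection
  stability; Mahalanobis orderings are insensitive to this uniform
  inflation.
* Mixed-signal accounting (`count_both`) assumes a colocalized pair is
  exactly one gene plus one CEP dot; higher-order stacks are not modelled.
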