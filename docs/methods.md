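# Methods

`wsisubtyper` implements a two-stage pipeline for calling the histological
subtype of a cervical-cancer whole-slide image (WSI): squamous cell
carcinoma (SCC) versus adenocarcinoma (AC).  Stage one classifies
individual tissue patches; stage two aggregates each slide's stream of
patch predictions into a slide-level call.  This note records the model,
the defaults and the design choices, and what the synthetic test bench
does and does not establish.

## Tiling and region restriction

Slides are tiled into non-overlapping 512×512-pixel patches at 20×
magnification.  Coordinates are 0-based, half-open windows
`[x, x+size) × [y, y+size)` with x = column, y = row.  Partial tiles at
the right/bottom edges are dropped so every patch has the exact shape the
classifiers expect.  When a pyramid stores 20× at a non-zero level, the
level whose inferred magnification is within ±1 of the target is used
directly; otherwise the nearest higher level is downsampled.  Plain RGB
images are accepted as single-level slides with a declared magnification,
which is how the synthetic bench drives the full code path.

Tumor annotations arrive as GeoJSON polygon feature collections in
level-0 pixel coordinates.  At inference, a patch enters the prediction
bag iff at least half of its area (`min_overlap_fraction = 0.5`,
boundary inclusive) lies inside the union of annotated polygons; the
same filter is available at training time.  Inter-observer annotation
agreement is measured by the Dice coefficient `2|A∩B|/(|A|+|B|)` (two
empty masks agree at 1.0 by convention); slides below 0.9 are flagged
for consensus review.

## Patch quality control

Five steps run in a fixed order; a patch stops at its first rejecting
step, and the audit trail records the step and the measured statistic.

1. **RGB background** — a pixel is background when its mean channel
   intensity exceeds 220 (white) or falls below 40 (black); reject when
   the background fraction exceeds 0.80.  The intensity cutoffs and the
   fraction are separate knobs because they measure different things:
   per-pixel extremity versus patch-level coverage.
2. **HSV glare** — reject when more than 70% of pixels are simultaneously
   low-saturation (S < 25/255) and high-value (V > 230/255).  The S/V
   cutoffs are calibration knobs (`QcConfig.hsv_sat_low`,
   `hsv_val_high`); the 70% fraction is the primary threshold.
3. **HED pen marks** — optical density `OD = −log10((I+1)/256)` is
   unmixed through the Ruifrok hematoxylin–eosin–DAB basis; the eosin
   plane is rescaled against a fixed reference concentration
   (`eosin_ref = 1.0` OD units, the scale of saturated ink) and clipped
   to [0, 1]; reject when the mean rescaled eosin value exceeds 0.90.
   Ink pigments load almost entirely on the eosin direction, while real
   eosin-stained tissue sits near 0.1 on this scale.
4. **Canny texture** — grayscale on the 0–255 scale, Canny edges with
   σ = 0.5 and hysteresis thresholds 100/200, then the variance of the
   {0, 255} edge map; reject below 7000.  A map with edge fraction p has
   variance 255²·p(1−p), so the cutoff corresponds to roughly 12% edge
   pixels — dense nuclear texture clears it, featureless or blurred
   patches do not.  σ = 0.5 targets fine chromatin-scale edges at 20×.
5. **Vahadane stain normalization** — survivors only; never changes a
   verdict.  A stain basis is learned from a reference patch by sparse
   non-negative dictionary learning on tissue-pixel optical densities
   (OD norm > 0.15, ≤5000 subsampled pixels, sparsity α = 0.1, seed 0,
   deterministic); columns are unit-norm, hematoxylin first (larger red
   OD).  Patches are re-rendered through the target basis with per-stain
   99th-percentile concentration matching.  By default the source
   appearance is described by the standard Ruifrok columns (closed-form,
   fast); per-patch source fitting is available for unusual stains.
   Concentrations are solved by least squares and clipped at zero; for
   images spanned by the basis, self-normalization is the identity to
   within one intensity level.

## Patch classifier

The built-in backbone, `tinycnn`, is a three-block CNN (3×3 convolutions
with 8/16/32 channels, ReLU, 2×2 max-pooling, global average pooling,
linear head; ≈6k parameters) implemented directly on NumPy, with inputs
downscaled to 64×64.  Training follows the study recipe: Adam, batch
size 64, L2 regularization λ = 0.001 added to the gradient, initial
learning rate 1e-4 with per-epoch exponential decay (γ = 0.95, a chosen
default — the decay factor is not pinned by the protocol), 50 epochs.
AC is the positive class; `p_ac ≥ 0.5` predicts AC, ties deliberately
favoring the minority class.  Train/validation splits are made at the
case level to prevent leakage between slides of one patient.

Inputs are standardized with fixed constants — `(I/255 − 0.65)/0.22`,
roughly the global mean and spread of H&E tissue patches — which keeps
first-layer activations well-scaled; without centering, the pooled
features are tiny, logits sit near zero, and short runs stall at the
ln 2 loss plateau.  Desk-scale runs (tests, worked examples) use 5–10
epochs at lr 3e-3: a 6k-parameter network training on a few hundred
patches sees only tens of Adam steps, so the 50-epoch schedule's
initial rate is replaced by one at which that short run converges.
At this scale convergence is still somewhat sensitive to
initialization; seeds for the documented runs are fixed.
The large named architectures (AlexNet, VGG19, ResNet-50, Inception-v3)
are registry names users can bind to their own GPU implementations via
`register_backbone`; they are not bundled, and backbone selection
(argmax of validation AUROC, ties to the smaller model) works over any
mix of candidates.

Grad-CAM heatmaps are the ReLU of the gradient-weighted sum of
final-convolution activations, upsampled to the patch and min–max
normalized; a map that is identically zero before normalization is
returned as zeros.

## Slide-level aggregation

Each slide is summarized by its ordered bag of patch predictions
(row-major scan order).  Three routes:

* **Majority voting** — most frequent token; exact ties go to AC.
* **Histogram** — 10 equal-width bins of `p_ac` over [0, 1], last bin
  right-closed, normalized to sum 1.
* **TF-IDF** — the slide is a document, patch calls are tokens.  Two
  token types cannot span ten dimensions with unigrams, so the
  vocabulary is n-grams of order 1–3, capped at the 10 n-grams with the
  highest document frequency (ties broken lexicographically).  tf is the
  raw count; idf is the smoothed `ln((1+n)/(1+df)) + 1`; rows are
  L2-normalized.  Short n-grams of the token sequence carry local
  spatial run structure (e.g. "AC AC AC" vs alternating calls) that the
  unigram frequencies alone would miss.

Features feed logistic regression, random forest, SVM (RBF), AdaBoost or
XGBoost with inverse-frequency class weights `w_c = N/(2 n_c)` (for the
imbalanced 245 SCC / 36 AC training corpus, `w_AC/w_SCC ≈ 6.8`).
Hyperparameters are grid-searched by stratified, case-grouped 5-fold CV
(seed 0) scored by AUROC; the default grids are: LR C ∈ {0.01, 0.1, 1,
10}; SVM C ∈ {0.1, 1, 10}, γ ∈ {scale, 0.01, 0.1}; RF trees ∈ {100,
300}, depth ∈ {None, 5}; AdaBoost estimators ∈ {50, 200}; XGBoost depth
∈ {2, 4}, estimators ∈ {100, 300}, lr ∈ {0.05, 0.1}.

## Evaluation

AC is the positive class throughout.  AUROC is the Mann–Whitney
statistic computed from midranks (identical to trapezoidal ROC
integration, ties counted half).  The panel — accuracy, sensitivity,
specificity, PPV, NPV, AUROC — reports undefined ratios as absent, never
as zero.  95% CIs are case-level percentile bootstraps (B = 2000, fixed
seed); resampling cases rather than patches respects the clustering of
patches within slides and slides within patients, and is typically
wider (more conservative) than patch-level resampling.  Degenerate
resamples with a single class are redrawn and counted.

Paired AUROCs are compared by the DeLong test via structural components
(midrank form), two-sided normal p-values, no multiple-testing
correction.  Calibration uses 10 equal-width bins with empty bins
omitted.  Decision-curve analysis reports
`NB(t) = TP/n − FP/n · t/(1−t)` on the grid t = 0.01…0.99 (step 0.01)
against the treat-all closed form `prev − (1−prev)·t/(1−t)` and the
treat-none zero line.

## Synthetic data bench

The generator emulates the statistical structure the pipeline consumes,
not histology.  Tissue patches are an eosin-pink canvas with shared
stromal speckle and chromatin noise (so every tissue patch clears the
edge-variance floor regardless of class), plus class-specific structures
whose contrast scales linearly with a separability parameter δ: solid
dark ellipses for SCC, rings with pale lumina for AC.  At δ = 0 the two
classes are drawn from the identical distribution.  Artifact patches are
engineered to trip exactly one QC step each: white/black → RGB; a
low-saturation, high-value bluish sheen whose mean intensity stays
inside the RGB band → HSV; forward-synthesized eosin-saturated ink →
HED; featureless pink texture → Canny.  Slides are mosaics of tiles with
a rectilinear tumor polygon covering a configurable fraction of the
grid; prediction bags flip each token away from the slide label with
probability 1−q.

Everything is driven by one integer seed and is bit-reproducible.
Because the class signal is planted and artifacts are engineered to
single thresholds, passing tests demonstrate that the pipeline's
plumbing, thresholds and statistics behave as specified — they do not
certify performance on real H&E material, where artifacts co-occur,
stain variation is continuous, and class morphology is vastly harder.

## Problem sizes used in tests and the reproduction script

Patch-classifier checks train on 400 64×64 patches for 5 epochs and
evaluate on 200 held-out patches; the slide-level check assembles 40
synthetic slides of 16 tiles each (tumor fraction 0.5, one white and one
blank artifact tile per slide) and calls them by majority vote.
TF-IDF recovery uses 200 training and 200 test bags at token fidelity
q ∈ {0.5, 0.7, 0.9}.  The DeLong null simulation runs 1000 replicates at
50 positives/50 negatives; bootstrap coverage uses 500 replications of a
binomial accuracy at n = 200, B = 2000.  QC golden tests run at the
native 512×512 patch size; classifier tests run at 64×64.

## Known limitations

* The TF-IDF vocabulary construction from binary tokens (n-grams, df
  cap) is one defensible reading of a 10-dimensional token featurization;
  alternatives (probability quantization, boolean tf) would differ.
* The eosin pen-mark rule depends on a global reference concentration;
  scanners with unusual color response may need `eosin_ref` recalibrated.
* Canny variance is resolution-sensitive; the 7000 default is calibrated
  for 512×512 at 20× (it happens to transfer to the synthetic 64×64
  tiles, but real low-resolution patches should be re-checked).
* The NumPy backbone is deliberately small; it demonstrates and tests the
  training recipe and explanations, not state-of-the-art patch accuracy.
* Pyramidal SVS reading requires a slide-reader backend; the package
  itself handles plain-image slides and pyramidal TIFFs whose levels are
  stored as separate images.
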