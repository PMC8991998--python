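# Methods

`betadisc` implements the image-analysis chain of a beta-sensitive
intraoperative probe built on a CMOS monolithic active pixel sensor: event
detection in detector frames, beta/gamma discrimination of the detected
event clusters, and per-pixel semantic labeling of whole frames.  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic data do and do not establish.

## Detection chain

A detector frame is a 2D intensity array in arbitrary detector units (ADU).
Acquisition starts with blank frames whose per-pixel arithmetic mean forms a
dark reference; every subsequent frame is dark-corrected by subtraction.
Negative residuals are clamped to zero — intensities feed [0, 1]-normalized
patches downstream, and sub-baseline excursions carry no signal.  The
corrected frame is binarized with a strict `>` threshold.  The threshold is
either absolute or `mu + k*sigma` with background statistics estimated
robustly (median and scaled MAD, so event pixels do not inflate the
estimate); `k = 5` by default, the usual seed/noise separation in pixel
detectors.

Events are found by 8-connectivity connected-components labeling
(`scipy.ndimage.label`) of the binary frame.  Each component becomes a
cluster: the tight bounding-box crop of the *corrected* frame, a member-pixel
mask, and the two scalar features **area** (member-pixel count) and **mean
intensity** (mean over member pixels, not over the full box, so that
`area x mean_intensity` equals the summed deposited intensity — the quantity
proportional to deposited energy).  Clusters touching the frame border are
kept and flagged; discarding them would bias area statistics.

## Synthetic events

No public cluster dictionaries exist for this detector, so the package
generates them:

* **beta** events are persistent 2D random walks (track length ~ N(10, 3)
  steps, directional persistence 0.9) depositing a total energy
  ~ N(2000, 500) ADU along the path with log-normal per-step jitter, then
  blurred with a Gaussian (sigma 0.8 px) emulating charge diffusion;
* **gamma** events are 1-2-pixel depositions of ~ N(300, 100) ADU with
  0.6 px diffusion.

The cluster mask is the set of pixels above a 30 ADU rendering threshold
(the largest connected component, if thresholding splits a weak track —
a detector would report those as separate events).  Frames are composed by
pasting member pixels onto a zero canvas at uniformly random positions
(bounding boxes kept `min_separation = 3` px apart by rejection), then
filling still-zero pixels with N(10, 2) background clipped at zero; blank
frames use the same background model.

A `separability` scalar in (0, 1] interpolates the gamma model toward the
beta model (energy, track length, persistence, diffusion alike); at 1 the
configured models apply, toward 0 the class distributions coincide and no
classifier can beat chance.  Two special study conditions are provided:

* `shape_only_config` — both classes share energy N(1200, 300) and length
  N(8, 2); betas are ballistic (persistence 0.95), gammas isotropic
  (persistence 0).  The two handcrafted features (mean intensity, area)
  then carry almost no class information while cluster *shape* does.
* `low_separability_config` — overlapping walks (beta length N(7, 3) vs
  gamma N(3, 2), energies N(1200, 400) vs N(800, 400), shared persistence
  0.7 and diffusion 1.0): short betas and long gammas are genuinely
  ambiguous, and a well-trained classifier reaches AUC ≈ 0.85.

What the generator does *not* emulate: calibrated charge transport in the
4 um epitaxial layer, Landau fluctuations, source spectra, pile-up, hot
pixels, or frame-rate effects.  Passing tests therefore demonstrate that the
algorithms behave as specified on data with the right qualitative structure
(elongated energetic betas vs compact faint gammas over Gaussian
background), not that the measured performance transfers to detector data.

## Lookup-table discriminator

Per-class 2D histograms of (mean intensity, area), each normalized to a
probability distribution, are divided element-wise (beta / gamma) to give a
selectivity map; a cluster whose feature bin has selectivity above a
threshold is called beta.  Policies the ratio needs: beta-only bins get +inf
(beta at any finite threshold), bins empty in both classes score 0 (gamma),
out-of-range clusters clamp to edge bins.  Default binning: unit-width
integer area bins to the largest training area, 64 equal-width intensity
bins over the pooled training range.  The raw ratio map is intentionally
unsmoothed, so it needs well-populated histograms: its test AUC approaches
its asymptote only with a few thousand training clusters per class.

## Patch classifier

Clusters are zero-padded into 24x24 patches: the bounding-box crop is
centered on a zero canvas (clusters larger than 24 px in either dimension
are dropped and counted; the fixed patch size presumes they are rare) and
divided by its own maximum, so each patch lies in [0, 1] and absolute
energy scale is removed.  The network is a reduced LeNet-5: three 3x3
convolution stages (8/16/32 filters, ReLU, same padding, 2x2 max pool;
24 -> 12 -> 6 -> 3), then dense layers of 128, 64, 32 and 2 units with a
softmax output; beta is the positive class (column 1).  The data protocol
is a stratified, seed-deterministic 60/20/20 train/validation/test split.

Training: categorical cross-entropy, Adam at 1e-3, batch 128, early
stopping on the validation loss with patience 10 and best-validation
weights restored.  The *initial* weights are scored as the first
best-validation candidate, so a warm-started fine-tune can never return
weights worse, by its own validation loss, than the weights it started
from.  Filter counts, optimizer and batch size are declared defaults (the
architecture source fixes only kernel sizes and dense widths); all are
configurable and recorded in checkpoints.

The networks themselves run on the package's own minimal numpy engine
(`betadisc.nn`): im2col 3x3 convolutions, 2x2 max pooling, dense layers,
softmax utilities and Adam, in float32, deterministic given the seed.
Gradient correctness is covered by finite-difference tests.

## High-specificity (WMW) loss

In surgery a false positive — a gamma called beta — falsely flags healthy
tissue, so the operating point sits at very low FPR and the relevant metric
is the partial AUC at FPR <= 0.02 (reported un-normalized, an area out of a
maximum 0.02).  The package trains for that region with the differentiable
Wilcoxon-Mann-Whitney surrogate

    R(x, y) = (gamma - (x - y))^p   if x - y < gamma, else 0
    L1 = sum_i sum_j R(x_i, y_j)

(margin gamma = 0.7, power p = 2), and its focused variant

    f(s) = (s - mu_s)^alpha  if s > mu_s else 0,   alpha = 1.1
    L2 = sum_i sum_j R(f(x_i), f(y_j))

where `mu_s` is the mean of the pooled scores of the current batch, treated
as a constant in the gradient (a self-referential mu gradient is degenerate).
The printed double sums are exposed as-is; training defaults to the
mean-per-pair reduction for batch-size-independent learning rates.

Two numerical decisions resolve the cold-start behavior of f: (i) on a
batch where every score sits at or below the pooled mean the L2 gradient
vanishes identically, so the step falls back to the un-mapped L1 gradient
until the scores spread; (ii) the recommended protocol for the L2 model is
a cross-entropy warm start (`TrainConfig.init_state`), since from-scratch
L2 training tends to collapse all scores to equality — the state the
fallback exists to escape but a poor use of the training budget.

On the synthetic low-separability conditions (with a 4:1 beta:gamma
training imbalance mirroring the strongly beta-heavy dictionaries this
probe produces), the cross-entropy solution is already at a local optimum
of the validated L2 objective: the fine-tune typically returns the warm
start unchanged, i.e. the L2 model *matches* rather than beats the CE model
at 2% FPR, while never being worse by its own criterion.  The package's
tests assert exactly that ordering (L2 >= CE in median partial AUC).

That the focusing map genuinely reshapes the operating region when there is
room to do so is demonstrated separately on a toy parametric scorer
(`experiments.toy_scorer_pauc_experiment`): two-feature data in which 80%
of the negatives are separated by one feature and a 20% hard subpopulation
only by the other.  The overall-ranking optimum of a logistic scorer leans
on the majority feature; fine-tuning the same scorer with L2 shifts weight
onto the feature that separates the hard negatives and raises the held-out
partial AUC at 2% FPR by roughly 30% in median over seeds.  The CNN's
near-parity on cluster data is thus a statement about those data — the
posterior-ranking CE solution leaves little tail room — not about the loss.

## Segmentation

Full frames are labeled per pixel (background / beta / gamma) by a fully
convolutional network: three 3x3 convolutions with 32 filters and ReLU,
then a 3-filter 3x3 convolution with per-pixel softmax; "same" padding
throughout keeps full resolution (no pooling).  Training frames are
synthesized 240x320 sensor outputs: dictionary clusters pasted at
non-overlapping random positions, still-zero pixels filled with N(10, 2)
background, the image scaled to [0, 1] by its maximum, and three binary
target channels that partition the frame.  The default population is 2 beta
+ 20 gamma clusters per frame — the clinical picture (few signal electrons
over an abundant gamma background) — which also keeps the two event
classes' per-frame pixel areas of the same order (betas are ~8x larger per
cluster).

The loss is the generalized dice loss

    GDL = 1 - 2 (sum_c w_c sum_n y p) / (sum_c w_c sum_n (y + p)),
    w_c = 1 / (sum_n y_c)^2

with weights treated as constants in the gradient; classes absent from an
image are excluded (w_c = 0) rather than infinite.

Optimizing GDL for three classes of wildly different areas is delicate, and
two training-scheme choices make it robust:

* **Crop training.**  The network is fully convolutional, so it trains on
  random 48x48 crops of the frames and transfers directly to
  full-resolution inference at a fraction of the cost.  Crops are biased
  toward planted clusters (probability 0.9 of centering on one, with
  positional jitter), and among event-centered crops 40% center on a beta
  cluster, so both rare classes appear regularly despite their low pixel
  fractions.
* **Per-crop loss.**  The GDL is computed per crop and averaged over the
  batch, not pooled across the batch's pixels.  A crop centered on one
  event class then usually contains no pixels of the other, whose weight
  drops out, and each class receives its full gradient in its own crops.
  With a batch-pooled objective the class with the materially smaller
  inverse-area weight loses the early race against the background channel:
  its pixels are captured by background, its softmax output collapses, and
  the gradient through the softmax — proportional to the class's own output
  probability — vanishes before the class has learned anything; no
  optimizer or learning rate tried escapes that state.  The per-crop
  reduction removes the race, and per-class dice then rises monotonically
  for every class and seed tried.

Early stopping
monitors the GDL on a fixed set of validation crops (patience 10); dice per
class is tracked each epoch, and reported dice is computed per image on
full frames and averaged (pixel-pooled dice is available as an option).

For ROC comparison with the patch classifier, each *ground-truth* cluster
(the evaluation uses known synthesized clusters; matching predicted
components would add an assignment problem the method does not define) is
scored by averaging, over its member pixels, the pairwise renormalization
p_beta / (p_beta + p_gamma) — the two-way softmax of the two log-scores.
Pixels where both event probabilities underflow carry no class information
and score 0.5.

## Evaluation

ROC curves sweep all score thresholds (`sklearn.metrics.roc_curve`, no
intermediate dropping) with beta as the positive class; AUC is trapezoidal,
which with tied scores processed as one step equals the pairwise WMW
statistic with half-ties — an equivalence asserted against a brute-force
pairwise oracle in the tests.  Partial AUC clips every ROC segment to
[0, fpr_max] (linear interpolation at the cut) and is reported
un-normalized.  Cross-dictionary ("transfer") evaluation needs no special
machinery: a fitted model scores any labeled dictionaries, including gamma
sources it never trained on.

## Problem sizes and limitations

Desk-scale defaults (single CPU): 4000 clusters per class for the
default-condition discrimination study, 2000 for the matched-feature study,
1600+400 training clusters and 2000+2000 fresh test clusters per seed for
the five-seed WMW comparison, 500 synthesized 240x320 frames (300/100/100)
for segmentation, 1250 clusters per class for the learning curve.  A
detector campaign would supply one to two orders of magnitude more; the
absolute AUC and dice values reported by the acceptance script characterize
the method on synthetic conditions and are not comparable to values
measured on real sensor data.  Known limitations: no pile-up handling (two
touching events are one cluster by construction of the algorithm), no
physically calibrated energy scale, the lookup table is unsmoothed by
design, and clusters larger than 24 px are excluded from classification.
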