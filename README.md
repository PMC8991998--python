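# betadisc

Beta/gamma event discrimination for CMOS active-pixel intraoperative
probes.

## The problem

Beta-sensitive intraoperative probes localize radiotracer-labeled tumor
tissue during cancer resection surgery by detecting short-range electrons
(including internal-conversion electrons from 99mTc).  The thin epitaxial
layer of a CMOS monolithic active pixel sensor keeps gamma sensitivity low,
but background gamma rays still convert at a finite rate, and a gamma event
misread as beta falsely flags healthy tissue as cancerous.  The sensor
reads out full frames in which each particle appears as a small cluster of
above-threshold pixels: electrons leave extended, energetic tracks; gammas
leave compact, low-energy depositions.  `betadisc` implements the complete
analysis chain that turns raw frames into discriminated events:

1. **frames** — dark-reference averaging, dark-current subtraction,
   thresholding (`mu + k*sigma` or absolute);
2. **cluster_detect** — 8-connectivity connected-components labeling,
   cluster extraction with (area, mean intensity) features, labeled
   HDF5 cluster dictionaries;
3. **feature_lut** — the classical discriminator: per-class 2D probability
   histograms of (mean intensity, area) divided into a selectivity map,
   thresholded to classify;
4. **cnn_classify** — a reduced LeNet-5 patch classifier on 24x24
   zero-padded, per-patch-normalized clusters, trained with categorical
   cross-entropy or a partial-AUC surrogate, stratified 60/20/20 splits,
   early stopping, cross-dictionary testing, learning curves;
5. **pauc_loss** — the Wilcoxon-Mann-Whitney AUC surrogate: pairwise hinge
   `R(x,y) = (gamma - (x-y))^p` for `x - y < gamma` (gamma=0.7, p=2), loss
   `L1 = sum_ij R(x_i, y_j)`, and the high-specificity variant `L2` on
   mapped scores `f(s) = (s - mu_s)^alpha` for `s > mu_s` (alpha=1.1);
6. **segmentation** — synthetic 240x320 sensor frames with 3-channel
   ground truth, a fully convolutional per-pixel classifier trained with
   generalized dice loss `GDL = 1 - 2 (sum_c w_c sum_n y p) /
   (sum_c w_c sum_n (y+p))`, `w_c = 1/(sum_n y_c)^2`, and per-cluster beta
   scores for ROC comparison;
7. **evaluation** — ROC (beta positive), trapezoidal AUC (= pairwise WMW
   statistic with half-ties), un-normalized partial AUC at FPR <= 0.02,
   model comparison reports;
8. **synth_events** — the synthetic event generator standing in for
   detector data: beta tracks as blurred persistent random walks, gammas as
   near-point depositions, full-frame composition with exact ground truth.

The two learned discriminators follow a model/results pattern:
`ClusterClassifier`, `SegmentationModel` and `LookupTableClassifier` are
built from data and `fit()` returns a results object carrying the fitted
state, training history, prediction/scoring methods and a `summary()`.

## Worked example

```python
import numpy as np
from betadisc import (
    default_config, sample_dictionaries, ClusterClassifier, SplitSpec,
    TrainConfig, LookupTableClassifier, roc, partial_auc,
)

cfg = default_config(seed=7)                      # study conditions
beta, gamma = sample_dictionaries(cfg, 1000)      # 1000 clusters per class

model = ClusterClassifier.from_dictionaries(beta, gamma, SplitSpec(seed=7))
results = model.fit(loss="ce", config=TrainConfig(seed=7))
print(results.summary())

scores = results.predict_scores(model.test)
curve = roc(scores)
print(f"classifier test AUC:        {curve.auc:.4f}")
print(f"partial AUC (FPR <= 2%):    {partial_auc(curve, 0.02):.5f}")

lut = LookupTableClassifier(beta, gamma).fit()
bt, gt = sample_dictionaries(default_config(seed=8), 400)
print(f"lookup-table AUC (fresh):   {roc(lut.scores(bt, gt)).auc:.4f}")
```

prints

```
Patch classifier (ce loss)
  parameters: 53282
  conv filters (8, 16, 32), dense (128, 64, 32) -> 2
  epochs run: 27 (best validation at epoch 16)
  final train loss: 0.0092724
  best val loss:  0.000852555
classifier test AUC:        0.9914
partial AUC (FPR <= 2%):    0.01970
lookup-table AUC (fresh):   0.8909
```

The classifier separates the two event classes almost perfectly on the
default synthetic conditions (AUC 0.99 on 200+200 held-out clusters); its
partial AUC of 0.0197 is close to the maximum possible 0.02, i.e. it keeps
high sensitivity even when at most 2% of gammas may be miscalled.  The
lookup table, restricted to the two handcrafted features, trails it —
the gap widens drastically when the class feature distributions are matched
(`shape_only_config`) so that only cluster shape is informative.

A command-line interface covers the same pipeline for on-disk data:

```sh
betadisc synth --seed 1 --frames 20 --clusters 2000 --out data/
betadisc detect --frames data/frames --label beta --out beta.h5
betadisc lut   --beta data/beta.h5 --gamma data/gamma.h5 --out lut.h5
betadisc train --loss ce --beta data/beta.h5 --gamma data/gamma.h5 --out model.npz
betadisc eval  --model model.npz --beta data/beta.h5 --gamma data/gamma.h5 \
               --fpr-max 0.02 --out report.json
```

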