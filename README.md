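# pathocell

Automated **tumour cellularity (TC)** estimation on H&E-stained breast-cancer
image patches, built from classical computer vision and machine learning.

After neo-adjuvant chemotherapy, pathologists grade the treatment response by
estimating the fraction of each tissue patch still occupied by malignant
cells — the tumour cellularity, a number in [0, 1] that feeds the residual
cancer burden index. Eye-balling TC is slow and rater-dependent; `pathocell`
computes it from the pixels. The pipeline:

1. **Colour separation** — the patch is converted to HSV and K-means splits
   it into three component images: eosin-pink stroma `Ip`, hematoxylin-blue
   nuclei `Ib` and the near-white background `Iba`. A configurable pink
   filter measures the stroma fraction.
2. **Nuclei segmentation** — a grayscale enhancement
   `In = K1·(Io ⊙ Im) + K2·Io + Im^γ` (with `Io` the luminance image, `Im`
   its 3×3-median-filtered version, γ = 0.1) darkens nuclei against a
   saturated-light background; Otsu's threshold binarises `In` and a
   marker-controlled watershed on the Euclidean distance transform splits
   touching nuclei.
3. **Feature extraction** — per nucleus: geometry (area, perimeter,
   roundness 4πA/P², equivalent-ellipse axes, eccentricity, orientation),
   co-occurrence texture and mean HSV inside the cell body; per
   neighbourhood window (30/60/90/120 px): plane concentrations
   `R = TW/TP` and 4-bin HSV histograms; per patch: global concentrations,
   HSV means and the pink-filter output; plus duct/cluster morphometrics.
4. **Key-parameter selection** — features are aggregated on the cellularity
   grid (0, 0.1, …, 1.0), correlated with TC by linear regression,
   cross-checked with a lasso fit, de-duplicated, and the survivors with
   |r| ≥ 0.80 form the key-parameter manifest (a default 22-feature
   manifest ships with the package).
5. **Classification** — SVM, KNN or AdaBoost on z-scored key-parameter
   vectors labels each nucleus benign or malignant.
6. **TC scoring** — every malignant nucleus is dilated by a disc
   (default radius 10 px ≈ a 5 µm cytoplasm rim at 0.5 µm/px) and
   `TC = |union of dilations| / |patch|`.

Because public challenge data cannot ship with the package, a synthetic
**phantom generator** renders H&E-like patches — pink stroma, white fat,
blue elliptical nuclei (benign: small and round; malignant: large, eccentric,
irregular), optional duct clusters — with pixel-exact ground truth and a
planted TC, so the whole pipeline is testable end to end.

## Worked example

Train a nucleus classifier on phantoms with known ground truth, then score a
fresh phantom cohort:

```python
import numpy as np, pandas as pd
from pathocell import (PhantomSpec, phantom_suite, analyze_patch, OracleClassifier,
                       train_classifier, estimate_cellularity)

grid = np.round(np.arange(0, 1.05, 0.1), 1)       # the 11 cellularity levels
spec = PhantomSpec(size=256)

train = phantom_suite(grid, n_per_level=1, seed=11, spec=spec)
tables, labels = [], []
for i, ph in enumerate(train):
    an = analyze_patch(ph.patch, patch_id=f"train_{i}")
    tables.append(an.table)
    labels.append(OracleClassifier(ph).predict(an.table))   # ground-truth labels
model = train_classifier(pd.concat(tables, ignore_index=True),
                         np.concatenate(labels), algorithm="svm", seed=0)

for i, ph in enumerate(phantom_suite(grid, n_per_level=1, seed=22, spec=spec)):
    res = estimate_cellularity(ph.patch, model, patch_id=f"patch_{i:02d}")
    print(f"{res.patch_id}: planted TC={ph.true_tc:.3f}  estimated TC={res.tc:.3f} "
          f"({res.n_malignant}/{res.n_nuclei} nuclei malignant)")
```

```
trained SVM on 816 nuclei: accuracy=0.994 TPR=0.995 AUC=1.000
patch_00: planted TC=0.000  estimated TC=0.000 (0/40 nuclei malignant)
patch_01: planted TC=0.113  estimated TC=0.112 (8/44 nuclei malignant)
patch_02: planted TC=0.210  estimated TC=0.211 (16/47 nuclei malignant)
patch_03: planted TC=0.311  estimated TC=0.322 (28/54 nuclei malignant)
patch_04: planted TC=0.402  estimated TC=0.391 (31/57 nuclei malignant)
patch_05: planted TC=0.510  estimated TC=0.504 (45/65 nuclei malignant)
patch_06: planted TC=0.602  estimated TC=0.600 (55/70 nuclei malignant)
patch_07: planted TC=0.707  estimated TC=0.714 (69/80 nuclei malignant)
patch_08: planted TC=0.801  estimated TC=0.788 (83/93 nuclei malignant)
patch_09: planted TC=0.901  estimated TC=0.896 (91/97 nuclei malignant)
patch_10: planted TC=0.999  estimated TC=0.999 (165/165 nuclei malignant)
```

The estimates track the planted cellularity across the whole range;
`evaluate_against_reference` on these pairs reports
`MSE=0.00005  ICC(2,1)=1.000 [1.000, 1.000]` (mean squared error and the
two-way absolute-agreement intraclass correlation with its 95% bounds — on
real material, where reference scores come from human raters, both numbers
degrade and the ICC's confidence interval is the figure of merit).

The same steps are available from the shell via the `pathocell` command
(`phantom`, `segment`, `extract`, `select`, `train`, `predict`, `evaluate`
subcommands; `pathocell --help` lists the options).

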