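# Methods

This note documents the models, parameter choices and numerical conventions
behind `pathocell`, and what its synthetic-phantom validation does and does
not establish about behaviour on real histology.

## Colour separation

Pixels are clustered on their HSV triples (all channels scaled to [0, 1])
with K-means, k = 3, k-means++ initialisation and a caller-supplied seed
(default 0) so runs are reproducible. Clustering happens per patch: H&E
staining intensity varies strongly between slides, and per-patch clustering
adapts to it without requiring cross-slide stain normalisation (which is
deliberately out of scope, as is optical-density stain deconvolution).

Cluster-to-role assignment is deterministic: the centroid maximising
`V − S` (bright and unsaturated) is the background `Iba`; of the remaining
two, the centroid whose hue is circularly closest to pink (hue 0.95 on the
wrap-around hue circle) is the stroma plane `Ip`, the other the nuclei
plane `Ib`. A patch with fewer distinct colours than clusters raises a
degenerate-clustering error rather than returning an arbitrary partition.

The pink stroma filter is a rectangular HSV gate, default
H ∈ [0.85, 1] ∪ [0, 0.05], S ∈ [0.05, 0.6], V ∈ [0.5, 1]. The interval is a
package default standing in for an interactively tuned threshold; every
bound is configurable, and the filter's output (stroma mask and its mean
concentration) is one of the global features.

## Nuclei enhancement and segmentation

The enhancement

    In = K1 · (Io ⊙ Im) + K2 · Io + Im^γ

is computed on [0, 1]-normalised intensities and clipped back to [0, 1];
`Io` is the luminance grayscale, `Im` its median-filtered version (3×3
default), and γ = 0.1 so the power-law term starts from a light background.
With the default K1 = 0.7, K2 = 0.3 every pixel brighter than roughly 0.27
in luminance saturates at 1 while nuclei-dark pixels stay below it, which
turns a cluttered colour image into a near-bimodal grayscale one. The
0.5/0.5 weighting is the documented untuned starting point; raising K1
while lowering K2 deepens the nuclei. Consequence of the clipping: the
enhancement's operating range is dark nuclei on a bright field — its
monotone-contrast property (more K1, no less contrast) holds in the
unsaturated regime and is tested there.

Binarisation is Otsu's threshold with the dark class taken as nuclei; a
constant image raises a degenerate-threshold error, which the composed
`segment_nuclei` maps to "no nuclei" (the correct answer for a
stroma-only field whose enhancement saturates everywhere). An optional
additive threshold offset is exposed for atypically lit material but
defaults to 0. An adaptive coupling between the threshold and the
strongest-correlated feature is conceivable but under-determined; plain
Otsu plus the offset knob is the implemented behaviour.

Touching nuclei are split by a watershed on the negated Euclidean distance
transform, seeded from the regional maxima that survive h-maxima
suppression with h = 2 px (8-connectivity). h = 2 splits two overlapping
discs whose neck is ≥ 2 px shallower than their centres while leaving a
single convex nucleus unsplit. Regions below `min_area` = 20 px²
(≈ 5 µm² at 0.5 µm/px, far below a lymphocyte) are discarded and labels
renumbered consecutively. The Jaccard index validates masks; two empty
masks score 1.0 by the perfect-agreement convention.

## Features

Coordinates are 0-based, x = column, y = row. Windows are axis-aligned
squares of side 30/60/90/120 px centred on the rounded nucleus centroid
with half-open extents, cropped at the image border; the concentration
denominator counts only in-image pixels, so border nuclei get unbiased
(if noisier) regional values and the table has no missing entries.

Roundness is 4πA/P² with the scikit-image perimeter estimator; values may
slightly exceed 1 on small discretised discs and are reported as computed.
Ellipse axes, eccentricity and orientation come from second central
moments (equivalent-ellipse convention), orientation in degrees from the
row axis. Texture is a symmetric, normalised gray-level co-occurrence
matrix at 8 levels and two offsets, (0, 1) and (1, 0), matching the two
numbered contrast/homogeneity features; it is computed by a small masked
counter (pairs with both pixels inside the nucleus) because the stock GLCM
implementations operate on rectangles only. Texture and mean HSV are taken
over the nucleus eroded by 1 px (falling back to the full mask when
erosion empties it) to avoid boundary colour mixing.

The "epithelial" regional concentration is defined here as the
concentration of the nuclei plane dilated by the cytoplasm radius used in
TC scoring (10 px default). The underlying notion — epithelium surrounds
nuclei — admits several formalisations; this proxy is the package's
choice and is labelled as such.

Duct/cluster detection follows set subtraction: candidate foreground is
the complement of the background plane; a closing (disc r = 7) merges
packed nuclei, an opening (disc r = 3) removes thin bridges, and connected
components with area ≥ 2000 px² containing ≥ 5 nucleus centroids are
reported with area, roundness, member count and mean centroid distance.
On a patch with no white background the candidate foreground is one large
tissue blob; the nucleus-count gate is what keeps sparse fields from
producing spurious clusters. Nuclei outside every cluster carry sentinel
zeros so the table stays dense. 4-bin HSV histograms are normalised to sum
to one (the raw-count alternative differs only by the window area, which
is nearly constant away from borders).

## Key-parameter selection

Rows are snapped to the 11-level cellularity grid (±0.025, off-grid rows
dropped; fewer than three levels is an error). Per feature, the level
means are regressed on the level by ordinary least squares; the Pearson r
of those ≤ 11 pairs is the correlation score (sign-agnostic thresholding,
since strong features can correlate negatively — stromal density falls as
cellularity rises). A zero-variance feature scores r = 0 and is flagged.

The lasso cross-check fits an L1-regularised regression of the raw rows'
TC on z-scored features with 5-fold CV (seeded folds). The regularisation
is chosen at the CV-minimum lambda rather than the sparser
one-standard-error lambda (available as `rule="1se"`): with several
correlated informative features — the typical situation for morphology
features that all track cellularity — the 1-SE rule collapses the group
to one representative, whereas CV-min retains every feature carrying
independent signal; the |r| ≥ 0.80 gate, not the lasso, is what rejects
noise. A feature is kept iff |r| ≥ 0.80, it is lasso-selected, and it
survives redundancy removal (greedy, strongest first: a feature whose
absolute Pearson correlation with an already-kept feature exceeds 0.95 is
dropped). The kept list is ordered by |r| descending.

A default 22-feature manifest (nucleus shape, smallest-window nuclei
concentration and HSV histograms, global colour/concentration summaries)
ships with the package so the classifier can run without a labelled
selection pass; on any particular dataset the selection procedure should
be re-run and will generally produce a different set.

## Classification and TC scoring

All classifiers operate on features z-scored with training statistics, so
predictions are invariant to affine rescaling of any input column.
Defaults — SVM: RBF kernel, C = 1, gamma scaled by feature count and
variance; KNN: k = 5, Euclidean; AdaBoost: 100 depth-1 stumps — are
implementation choices, all overridable. "Malignant" is the positive
class; `decision_scores` returns a monotone malignancy score (decision
function or positive-class probability). No class re-weighting is applied
by default, appropriate for training sets built with roughly balanced
classes.

TC is the area fraction of the union of malignant-nucleus dilations by a
Euclidean disc {d ≤ r}, r = 10 px by default (≈ 5 µm cytoplasm rim at
0.5 µm/px), clipped at borders. The union (not the sum) is forced by the
area-ratio definition: overlapping cytoplasm estimates count once. Benign
nuclei contribute nothing. The dilation is computed exactly as a distance
transform threshold, so TC is bitwise reproducible and monotone in r.

Prediction/reference agreement is summarised by MSE and ICC(2,1) — the
two-way, single-rater, absolute-agreement intraclass correlation, the
standard choice for comparing one automated method against one rater —
with its analytic 95% bounds, plus per-reference-level dispersion
summaries for boxplot-style inspection.

## The phantom generator

Phantoms emulate the compositional structure of a 20×, 0.5 µm/px breast
H&E patch: an eosin-pink stroma field (default RGB (230, 160, 200)),
white fat blobs covering ~5% of the area, hematoxylin-blue nuclei
(default (45, 35, 105)) and optional duct clusters of packed nuclei.
Benign nuclei are small near-circular ellipses (semi-axis 4–6 px);
malignant nuclei are larger (7–11 px), eccentric (0.5–0.85) with a
low-order harmonic boundary perturbation. Encoding malignancy purely
geometrically is a modelling choice of the fixture: it makes the
morphology features genuinely discriminative while keeping one shared
chromatin colour, so the intensity histogram stays bimodal the way the
segmentation stage assumes. Per-structure colour jitter (sd 6, truncated
at ±1.5 sd) and per-pixel Gaussian noise (sd 5 of 255) provide texture
without ever driving a nucleus past the contrast margin the generator
advertises — an invariant the segmentation tests rely on. Placement is
rejection sampling with a 2 px minimum separation; an impossible packing
raises a placement error rather than silently under-delivering.

`phantom_suite` plants TC targets by adding malignant nuclei one at a time
while maintaining the exact dilated-coverage union incrementally, stopping
once the target is reached; benign nuclei fill remaining space in
proportion to 1 − target. The stored `true_tc` is recomputed from the
planted masks by the same dilation operator used for scoring, so
ground-truth self-consistency is exact by construction. Unreachable
targets (packing saturates first) return the best achievable coverage.

**What phantom results do and do not show.** Phantoms have sharp nucleus
boundaries, a single stain palette, no out-of-focus blur, no overlapping
nuclei beyond the touching-pair constructions, and no mimics (apoptotic
debris, stromal cells with enlarged nuclei). Passing the phantom suite
demonstrates that the pipeline's machinery is correct — segmentation
recovers what its contrast assumptions cover, features measure what they
claim, selection finds planted signal, classification separates separable
classes, and the TC arithmetic is exact — not that the defaults transfer
to scanner data, where stain normalisation, threshold tuning and a
dataset-specific selection pass are expected.

## Problem sizes and runtime choices

Tests and the acceptance script run phantoms at 192–256 px (the generator
default is 512 px, the nominal patch size): at 0.5 µm/px this is a
96–128 µm field, ample for dozens of nuclei per patch, and keeps the full
verification suite in the low minutes on one CPU. End-to-end TC recovery
uses 11 training phantoms (one per grid level, ~800 nuclei) and 30 test
phantoms; segmentation recall uses 30 phantoms of 18 nuclei each.

## Known limitations

- The enhancement's clipping makes segmentation insensitive to nuclei
  lighter than ~0.27 luminance under default weights; such material needs
  the K1/K2 or threshold-offset knobs.
- Watershed occasionally oversegments strongly irregular malignant nuclei
  (boundary lobes create multiple distance-transform maxima); the h = 2
  suppression bounds but does not eliminate this.
- Duct detection on fully tissue-covered patches reports one large region
  gated only by nucleus count; it separates ducts cleanly only when white
  background delimits them.
- ICC confidence bounds assume the usual two-way ANOVA model; with
  near-perfect agreement the F statistics degenerate and the bounds are
  reported as NaN.
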