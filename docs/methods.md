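# Methods

`sonotex` implements a complete computer-aided-diagnosis workflow for
B-mode liver ultrasound: synthetic speckle phantoms stand in for clinical
sonograms, a region of interest is segmented, five texture-feature panels
are extracted, a subset of features is selected, a small neural network is
trained to separate normal from abnormal livers, and the feature panels are
compared by confusion-matrix and ROC analysis.  This note records the
models, the parameters that matter, the numerical conventions, and the
design decisions that were genuinely open.

## Synthetic sonograms

Clinical B-mode liver data of the kind this workflow targets is not
publicly available, so the package generates its own study population.  The
image model is fully developed speckle: a complex zero-mean white Gaussian
scatterer field is low-pass filtered with a Gaussian kernel whose standard
deviation is the class *coarseness* (pixels), and the envelope (magnitude)
of the filtered field is taken.  A filtered complex Gaussian field is still
Gaussian, so the envelope is Rayleigh-distributed at every pixel; the field
is rescaled so its in-liver mean equals the class *echogenicity* (on the
8-bit intensity scale).  The liver itself is a convex 10-vertex polygon
with per-case jitter, covering roughly half of a 128 x 128 frame; the
background is fixed at intensity 8 so segmentation has a real gradient to
find.  Cirrhotic inhomogeneity is modelled as a multiplicative nodularity
field: `1 + a * g` where `g` is unit-variance Gaussian noise smoothed at a
12-px scale and `a` is the nodularity amplitude.

Class presets encode the qualitative contrasts of the clinical literature —
fatty liver hyperechoic with fine texture, cirrhosis hypoechoic, coarse and
nodular, hepatomegaly an enlarged but otherwise normal-textured liver:

| class        | echogenicity | coarseness (px) | nodularity | liver length (cm) |
|--------------|-------------:|----------------:|-----------:|------------------:|
| normal       | 105          | 1.2             | 0          | 13.5 +- 0.8       |
| fatty        | 160          | 0.8             | 0          | 14.0 +- 1.0       |
| cirrhosis    | 70           | 2.0             | 0.35       | 12.5 +- 1.0       |
| hepatomegaly | 105          | 1.2             | 0          | 17.5 +- 1.0       |

The magnitudes are invented — the clinical sources are qualitative — and
are configuration, not constants.  Per-case variation comes from a 5%
multiplicative echogenicity jitter and the length draws above.  The default
dataset is 30 normal / 10 fatty / 10 cirrhosis / 10 hepatomegaly, with a
separate 20-normal / 20-abnormal held-out set, mirroring the study design
the package is modelled on.  Everything derives deterministically from one
master seed.

What the phantom does *not* model: beamforming and attenuation artifacts,
time-gain compensation, shadowing, probe-dependent point-spread anisotropy,
lesions and ascites, and operator variability in plane selection.  Passing
the downstream classification checks therefore demonstrates that the
pipeline recovers the texture contrasts it was given, not clinical
performance on real sonograms.  Hepatomegaly in particular is separable
only through the liver-length scalar, by construction — which is exactly
why the mixed panel dominates the per-panel comparison here.

## Preprocessing

Cropping is plain rectangular array slicing (0-based, row-major, pixel
centers at integer coordinates).  Segmentation is a greedy discrete active
contour: each vertex in turn moves to the candidate position that minimizes
the sum of the energy terms it participates in,

    E = sum_i alpha |v_i - v_{i-1}|^2 + beta |v_{i-1} - 2 v_i + v_{i+1}|^2
               - gamma * edge(v_i),

with `edge` the max-normalized gradient magnitude of the image smoothed at
sigma = 2 px.  Defaults: alpha = 0.10, beta = 0.02, gamma = 1.0, 60
vertices, convergence when the mean per-sweep vertex displacement drops
below 0.05 px (at most 500 sweeps).  Because a move is accepted only if it
lowers the energy terms it touches, total energy is non-increasing across
sweeps.  The candidate set is one key numerical choice: a vertex considers
stay plus eight directions at radii 1, 0.5 and 0.25 px.  The sub-pixel
rings are required, not cosmetic — the internal-energy gain of a lone
vertex move scales with the local polygon sag (typically 0.1-0.5 px), so a
pixel-only search freezes the contour on gradient-free regions; with the
fine rings the internal terms contract the contour until the edge term
captures it, giving the deform-to-boundary behaviour of semi-automatic
snake tools without a balloon force.  Initialization is the inscribed
ellipse of the cropped rectangle (automatic) or a user-supplied contour.

"Background subtraction" is exclusion, not value arithmetic: pixels outside
the contour are flagged and zeroed in exported rasters, and no feature
computation ever reads them.  The operation is idempotent and leaves
in-mask values untouched.

## Texture features

All features are computed strictly over in-mask pixels.

**Intensity histogram (6).** Mean, standard deviation, average energy
`sum p(i)^2`, Shannon entropy in bits, skewness, and non-excess kurtosis of
the 256-bin in-mask histogram.  Skewness and kurtosis are defined as 0 when
the standard deviation is 0.

**Co-occurrence / GLCM (22).** Intensities are quantized to G = 64
equal-width bins over [0, 255]; pairs at distance d = 1 are counted only
when both pixels are in-mask, accumulated symmetrically, normalized, and
the feature set is averaged over the four directions 0/45/90/135 degrees.
Indices are 1-based; entropies use the natural logarithm.  The panel is the
classical Haralick/Soh/Clausi set: autocorrelation, contrast, correlation,
cluster prominence, cluster shade, dissimilarity, energy, entropy, two
homogeneity variants (denominators `1+|i-j|` and `1+(i-j)^2`), maximum
probability, sum of squares, sum average, sum variance (centred on the sum
entropy, following the classical definition), sum entropy, difference
variance, difference entropy, the two information measures of correlation
(IMC1 is 0 when max(HX, HY) = 0; the IMC2 radicand is clamped at 0),
inverse difference (the `|i-j|` form, kept as its own named feature),
inverse difference normalized (`1+|i-j|/G`), and inverse difference moment
normalized (`1+(i-j)^2/G^2`).  Correlation is defined as 0 for a
zero-variance matrix.

**Run length / GLRLM (11).** Intensities quantized to M = 16 levels; maximal
runs are counted along each of the four directions, breaking wherever the
scan line leaves the mask; the run-length axis is truncated at the longest
observed run.  The eleven emphases (SRE, LRE, GLN, RLN, RP, LGRE, HGRE,
SRLGE, SRHGE, LRLGE, LRHGE) use 1-based gray-level indices and are averaged
over the four directions.

**Invariant moments (7).** Hu's seven invariants of the intensity-weighted,
in-mask image: raw moments with intensity as mass, central moments about
the intensity centroid, normalization
`eta_pq = mu_pq / mu_00^(1+(p+q)/2)`, then the standard 1962 combinations.
They are exactly invariant to translation and lattice rotation and stable
to about 1% under 2x resampling.

**Mixed (47).** Concatenation of the four families plus the per-case liver
length, in a fixed name order.  How liver length would be measured on a
real sonogram is out of scope; it enters as a given per-case scalar.

## Feature selection

The evaluator is the CFS merit
`M_S = k r_cf / sqrt(k + k (k-1) r_ff)` over a candidate subset: mean
feature-class association in the numerator, mean pairwise feature
association in the denominator.  The association measure is the genuinely
open design choice here, and it matters.  With absolute Pearson correlation
(provided as `measure="pearson"`), any feature whose relation to the class
is two-sided — brightness, which fatty livers raise and cirrhotic livers
lower relative to normal — correlates near zero with the binary label and
is discarded, as is liver length, whose relevance is confined to the
hepatomegaly minority.  The default (`measure="su"`) is therefore
symmetrical uncertainty `2 I(a;b) / (H(a)+H(b))` on features discretized by
the Fayyad-Irani MDL criterion: the supervised discretization finds the
informative cut(s) of a feature regardless of direction, collapses
uninformative features to a single bin (association exactly 0), and does
not dilute minority-subgroup features with arbitrary bin entropy.  This is
the pairing classical CFS implementations actually use.

Search is either a simple genetic algorithm (population 20, 20 generations,
crossover 0.6, per-bit mutation 0.033, roulette selection on shifted
fitness, elitism of one, deterministic per seed) or uniform random subset
sampling with a fixed budget (exhaustive when the budget covers the subset
lattice).  Merit ties break toward the smaller subset, then the
lexicographically smaller bitmask.  One consequence worth recording: two
exact copies of a feature score the *same* merit as the single copy
(`r_ff = 1` makes the formula collapse), so deduplication is delivered by
the tie-break, not by the merit itself.

## Classifier

A two-layer feed-forward network with sigmoid hidden and output units:
inputs min-max normalized to [-1, 1] on the training partition (held-out
data clipped to the same range), 10 hidden units by default, two one-hot
output units (normal, abnormal), mean-squared-error loss, weights
initialized uniform(-0.5, 0.5) per seed.  Training is Moller's scaled
conjugate gradient: conjugate directions with a second-order step-size
estimate (sigma = 5e-5) regularized by an adaptive Levenberg-Marquardt
damping term (initial lambda = 5e-7), no line search, with a periodic
restart every `n_params` iterations.  Stopping: 1000 epochs, gradient norm
below 1e-6, or six consecutive validation-MSE increases (the classic
early-stopping patience), after which the best-validation weights are
restored.  The data split is stratified 80/10/10 by largest remainder.  A
retraining loop repeats the fit with incremented seeds (up to 5 by default)
until validation accuracy reaches 90%, returning the best attempt.  Hard
labels take the argmax of the two outputs with exact ties resolved to
abnormal — for a disease screen the false alarm is the cheaper error.  ROC
analysis uses the abnormal unit's score.

## Evaluation

Abnormal is the positive class throughout.  Accuracy, sensitivity (TPR),
specificity (TNR), FPR, FNR and misclassification rate follow the usual
confusion-matrix definitions; zero-denominator rates are defined as 0 with
a warning.  The ROC curve is traced over every distinct score (ties
grouped), starts at (0,0) and ends at (1,1), and its trapezoidal area
equals the normalized Mann-Whitney pair count — an identity the tests check
to 1e-12.  The per-panel comparison reports train-pool and held-out
accuracy/TPR/TNR/FNR side by side and flags the best held-out accuracy
(all rows on a tie).

## Pipeline and problem sizes

`run_pipeline` is a pure function of its configuration: per-stage seeds
(pool data, held-out data, selection, training) derive from one master
seed, and a rerun reproduces every table byte for byte.  The training row
of the comparison is computed on the full 60-case pool (whose internal
80/10/10 split drives training dynamics), the testing row on the 40-case
held-out set.  By default the pipeline uses the generator's ground-truth
polygon as the ROI (`segmentation="mask"`); `segmentation="snake"`
re-derives each mask with the active contour.  The mask route is the
default because the snake reproduces the generator's polygons at Jaccard
0.90+ (verified separately on disk and liver phantoms), so repeated
whole-pipeline experiments — the 100-master-seed classification check runs
the complete pipeline 100 times — spend their time where the variance is.
Images are 128 x 128; at these sizes one full pipeline run takes on the
order of a second.

## Known limitations

- The phantom's texture contrasts are large relative to its within-class
  variation; held-out accuracies near 100% for the mixed panel say nothing
  about clinical effect sizes.
- GLCM quantization (G = 64), distance (d = 1), direction averaging, GLRLM
  levels (M = 16) and the histogram log base are conventions; other choices
  change feature values and any comparison against externally computed
  tables must match them.
- The greedy snake has no balloon force; with an initialization far from
  any edge and high curvature weight it can stall on flat regions (the
  sub-pixel candidate rings mitigate, not eliminate, this).
- Two-class output only; the per-disease labels exist in the synthetic
  manifests but the classifier treats them only as normal/abnormal.
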