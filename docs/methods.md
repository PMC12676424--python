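# Methods

`layerlens` implements a tissue-layer-wise occlusion framework for explaining
volumetric ultrasound classifiers, together with the curriculum-adaptive
re-weighting training scheme it was designed around, and a synthetic
layered-phantom generator that makes every stage of the pipeline testable
without clinical data.  This note records the models, the defaults and why
they were chosen, and the limits of what the phantom experiments establish.

## The explanation model

A scan is one or two co-registered 3D grids over the same voxel lattice: a
B-mode echogenicity channel and, optionally, a shear-modulus channel derived
from shear-wave elastography speed maps via μ = ρc² with ρ = 1000 kg/m³.
An integer label map partitions the volume into background plus six tissue
layers, superficial to deep: dermis (1), superficial fat (2), superficial
fascial membrane (3), deep fat (4), deep fascial membrane (5), muscle (6).
Arrays are indexed `(depth, height, width)` with depth increasing into the
tissue.

For a classifier `C` with log-odds output and a layer mask `M_i`, the
per-scan directional occlusion delta is

    Δ_i = logit(C(I)) − logit(C(I ⊙ (1 − M_i)))

where occlusion zeroes the layer's voxels in every channel simultaneously
(the channels are concatenated before classification, so a layer is either
present or absent as a whole).  Across a dataset of n scans:

* `PDSS_i = mean(max(Δ_i, 0))` — how strongly the layer's presence pushes
  predictions toward the positive class;
* `NDSS_i = −mean(min(Δ_i, 0))` — toward the control class;
* `SS_i = mean |Δ_i| = PDSS_i + NDSS_i` — overall importance.

The absolute-value convention for SS is deliberate: it is the only reading
under which a single non-negative importance score decomposes exactly into
the two non-negative directional scores.  Volume-adjusted variants divide
each scan's delta by that scan's layer voxel count *before* averaging
(information density rather than bulk); scans in which a layer is absent
contribute Δ = 0 to the raw scores and are excluded from the
volume-adjusted average, and a layer absent from every scan is reported as
undefined rather than zero.  The 95% CI for SS is the normal approximation
mean ± 1.96·SE over scans; a seeded 1000-resample bootstrap is available
(`ci_method="bootstrap"`), and on phantom data the two agree to the third
decimal.

Pairwise structure is summarised two ways: the Pearson correlation of the
per-scan |Δ| sequences of two layers (signed deltas behind a flag), and the
occlusion interaction score

    OIS_ij = (SS_ij − (SS_i + SS_j)) / max(SS_i + SS_j, ε),   ε = 1e−8

with `SS_ij` the dataset score of occluding both layers at once.  A
positive OIS means joint occlusion hurts more than the parts (synergy), a
negative one less (redundancy).  When `SS_i + SS_j < ε` the value is
reported with a degenerate-denominator flag rather than silently exploding.
For any classifier whose logit is affine in the voxel values, joint deltas
are exactly additive and (when the two layers' deltas share a sign) OIS is
identically zero — the package's main closed-form oracle.

## Faithfulness evaluation

Given a layer ranking, the insertion curve starts from an all-zero volume
and restores the ranked layers cumulatively, recording the logit after each
step (background voxels stay zero, matching the occlusion convention); the
deletion curve starts from the intact scan and removes them.  Both curves
carry the k = 0 anchor — without it the trapezoid rule below would be
undefined — so with K layers each has K + 1 points:

    AUC_ins = (1/K) Σ_k (i_{k−1} + i_k)/2,   AUC_Δ = AUC_ins − AUC_del,
    IROF = max_k i_k / (min_k d_k + ε).

Logits are signed, so IROF's quotient is ill-behaved when the deletion
minimum is non-positive; it is computed as defined but flagged.  Dataset
metrics are arithmetic means of per-scan metrics.  For an affine model the
curves obey the anti-symmetry `i_k + d_k = i_0 + i_K`, and ranking by true
per-layer contribution provably maximizes AUC-insertion (verified
exhaustively over all 720 permutations in the tests).  Note the mirror
identity `d_k = i_{K−k}` holds only in the equal-contribution special case.

## CARN training

The classifier is trained with two cooperating mechanisms:

* **Self-paced curriculum.**  Each sample keeps an exponentially smoothed
  difficulty `L ← βL + (1−β)l` (β = 0.9), initialized at the first observed
  loss so the average is not biased toward zero; never-visited samples sort
  as easiest so the pool genuinely grows.  Epoch e trains on the
  `N_e = round(f_e N)` easiest samples, with exposure ramping linearly,
  `f_e = f_min + (1−f_min)·e/(E−1)`, from f_min = 0.2 to 1.  Ties break by
  stable registration order; difficulties of unselected samples are frozen
  between epochs.
* **Adaptive intensity re-weighting (AIR).**  A trainable generator G maps
  the scan to a voxel-weight grid and the classifier sees `G(I) ⊙ I`;
  binary cross-entropy is backpropagated jointly through both.  The
  generator output passes through a sigmoid, so weights lie in (0, 1):
  re-weighting can attenuate but never sign-flip image content.

Predictions are aggregated up the scan hierarchy
(scan → site → side → visit → patient) by arithmetic averaging of
probabilities, with the group logit recomputed from the mean probability;
the aggregate therefore always lies within the member range.

### Desk-scale architectures

All models are NumPy modules with analytic gradients, sized for volumes of
16–48 voxels per axis:

* `VoxelGateGenerator` — gate `g = sigmoid(v + s·mean_c(x))` with a learned
  spatial bias map and input-sensitivity map;
* `LinearVolumeClassifier` — affine logit over voxels,
  `logit = mean(w ⊙ x) + b`.  The mean (not sum) keeps the logit scale and
  hence the effective optimizer step independent of voxel count;
* `SlabQuadraticClassifier` — mean-pools the volume into equal depth slabs
  per channel and applies `logit = w·f + f'Uf + b`.  `U` carries
  off-diagonal terms only: a learned pairwise dependence must then appear
  as a cross term, which makes interaction attribution identifiable —
  with free diagonal terms an XOR-type pair code can equally be fit by
  diagonal curvature (e.g. −(f_i−f_j)²), and the sign of the measured
  interaction becomes an artifact of which representation the optimizer
  happens to find;
* `SlabLinearClassifier` — the additive low-capacity member,
  `logit = w·f + b`; each layer's occlusion delta then depends only on
  that layer's own content.

Training uses Adam with decoupled (AdamW-style) weight decay.  The decay
matters for interpretation, not just regularization: during early
calibration the optimizer spreads a transient offset across all voxels in
proportion to brightness, and without decay those weights persist and give
bright-but-uninformative layers spurious occlusion saliency.  Defaults:
learning rate 1e−2, weight decay 1.0 (per-step shrink lr·wd = 1%), batch 8.
These suit the shallow NumPy models; deeper GPU-scale networks conventionally
use rates around 1e−4, which remain available through the config.  Model
inputs are zero-padded to a common shape, and the shear-modulus channel is
rescaled Pa → kPa at dataset assembly so the channels share a scale — a pure
scaling, so the "occluded voxel = 0" convention is untouched.  The
probability→logit transform clips probabilities to [1e−6, 1 − 1e−6].

## Validation suite

* **Randomization sanity.**  Every parameter is re-drawn from the
  architecture's seeded initialization and the saliency table recomputed;
  the collapse ratio (trained / randomized mean |SS|) should exceed 1 by a
  wide margin when explanations derive from learned structure.  The trained
  parameters are restored afterwards.
* **Directional association.**  Per layer, side-level scores (mean PDSS or
  NDSS over the side's scans) enter a univariate logistic model
  `logit P(MP=1) = β0 + β1 S`, fitted by maximum likelihood with Wald 95%
  CI and p-value (likelihood-ratio p behind a flag).  The pre-specified
  directional criterion is β1 > 0 with p < 0.05 for PDSS; for NDSS the
  expected sign defaults to β1 < 0 (a control-driving layer should lower
  MP odds) and is configurable.  Complete separation is detected and
  refitted with a ridge-penalized Newton iteration (slope-only penalty),
  flagged, never fatal.  p-values are per-layer and uncorrected by default;
  a Benjamini–Hochberg helper is provided.  ROC AUC uses the Mann–Whitney
  formulation with ties counted ½.

## The phantom generator

Phantoms emulate the *structure* of a paraspinal multimodal ultrasound
cohort, not its image physics.  Geometry: six contiguous depth slabs (equal
sixths of the depth by default) whose interfaces are displaced by a smooth
random field bounded by `interface_wobble` voxels (1 by default), with
ordering and one-voxel minimum thickness enforced so every layer survives in
every column.  Texture: B-mode is per-layer mean echogenicity times
unit-mean gamma speckle with shape 4 (a standard fully-developed-speckle
surrogate; coefficient of variation 0.5); the modulus channel is the
per-layer μ = ρc² value plus Gaussian-smoothed additive noise (sd 300 Pa),
clipped at zero.  Default per-layer B-mode means (1.2, 0.8, 1.5, 0.7, 1.6,
0.9) and shear speeds (2.5, 1.8, 3.0, 1.6, 3.2, 2.2) m/s encode the
qualitative anatomy — echogenic membranes, hypoechoic fat, stiff muscle —
and are free parameters, not estimates of any real cohort.

Hierarchy: patients × visits × 2 sides × sites × repetitions, with three
B-mode and two SWE repetitions per site by default; repetition r carries an
SWE channel when r ≤ swe_reps.  Disease status is assigned per
(patient, side) with the configured prevalence (0.5) and held fixed across
visits; tender/trigger point counts are drawn for positive sides and the
scan/visit labels derived from them by the same rules the cohort module
applies to real metadata.  One layer geometry is drawn per
(patient, side, site) and shared by its repetitions (co-registration by
construction).

Signal geometries:

* **additive** — each signal layer's mean shifts independently in
  positives (default: layer 5, +0.5 B-mode, +2000 Pa);
* **synergistic** — a per-side latent sign s shifts the designated pair
  with the same polarity in positives and opposite polarity in controls:
  each layer's marginal distribution is class-independent, the pair's
  product is perfectly class-informative;
* **redundant** — the identical shift duplicated in both layers.

## Standard desk-scale studies

The `experiments` module pins one set of study conditions, used by the test
suite and the acceptance script alike; every study derives its sub-seeds by
hashing a single base seed.

| study | phantom | classifier | measured |
|---|---|---|---|
| planted-layer | 32³, 20 patients, additive layer 5 | voxel-linear + gate, 20 epochs | held-out side AUC; layer 5 top SS rank over 10 replicates |
| interaction | 24³, 12 patients, pair (4,5), B-mode channel | slab-quadratic (off-diagonal) | OIS sign of the pair over 10 replicates per mode |
| faithfulness | 32³, graded signal in layers 5/3/1 (0.6/0.35/0.2) | voxel-linear + gate | saliency vs random ranking AUC-Δ over 100 held-out scans |
| sanity | as planted-layer | voxel-linear + gate | collapse ratio over 10 re-init seeds |
| association | 24³, additive layer 5 at 0.15 | slab-linear | criterion power at n = 100 sides (20 replicates); noise-layer rejection rate (200 replicates) |

Three of these conditions are themselves informative about the method:

* the faithfulness study plants a *graded multi-layer* signal because with
  a single informative layer a random permutation reproduces the optimal
  ranking's AUC-Δ whenever it happens to place that layer first, so no
  ranker can win ≳ 5/6 of trials;
* the interaction study restricts training to the B-mode channel (where the
  pair code is planted) and takes the best of three seeded optimizer
  restarts by final training loss, because the XOR-type fit is
  optimization-hard at this scale; restart selection never sees the
  measured OIS;
* the association study uses the slab-linear classifier: the full
  voxel-weight model memorizes the weak-effect training cohort instead of
  generalizing, and any classifier with cross-layer terms leaks class
  signal into an uninformative layer's occlusion delta, which would make
  the noise-layer level test measure the architecture rather than the
  statistic.  The level check scores whichever directional score
  (PDSS/NDSS) is non-degenerate for the trained model; under the null both
  are class-independent, so the test level is unaffected.

## What the phantom results do and do not show

Passing these studies establishes that the pipeline's mechanics are sound:
occlusion scores recover a planted signal's location and interaction sign,
the faithfulness harness separates informative from arbitrary rankings,
saliency collapses under weight randomization, and the association test has
power against real effects and holds its level against null ones.  The
phantoms deliberately omit depth-dependent attenuation, shadowing,
refraction and speckle correlation, anisotropic resolution, segmentation
error in the label maps, and inter-patient anatomical variability beyond
interface wobble — so desk-scale numbers (AUCs near 1, collapse ratios in
the 10⁴ range) characterize the implementation under clean conditions and
do not transfer to clinical data, where all of the above compress
performance.

## Numerical choices and degenerate inputs

Logits use the natural log.  N_e rounds half-up with a floor of one sample.
Label-map interface comparisons carry a 1e−9 tolerance so exact integer
boundaries are not lost to cumulative-sum rounding.  Saliency of an empty
(zero-voxel) layer is an exact zero delta; OIS with a vanishing denominator
and IROF with a non-positive deletion minimum are flagged rather than
suppressed; Pearson correlations with fewer than three scans or zero
variance are NaN.  Single-class training sets warn and proceed.  The
pipeline stamps every CSV with the run seed and a hash of the full config;
re-running an identical config reproduces identical outputs.
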