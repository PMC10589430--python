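# Methods

`strokecast` predicts post-stroke motor outcome in mice from two early
measurements — atlas-segmented MRI lesion topography and the subacute
behavioral deficit — and quantifies which brain regions drive that
prediction. Because the package must be testable without animal data, it
ships a synthetic cohort generator whose ground truth the analysis provably
recovers. This note documents the models, the defaults and why, and what
the synthetic results do and do not show.

## The prediction problem

Each animal undergoes transient middle-cerebral-artery occlusion (MCAO),
T2-weighted MRI on day 1 (yielding a binary lesion mask registered to a
reference atlas), and daily staircase skilled-reaching tests. Performance
is the percentage of pellets retrieved per paw, expressed as percent of the
animal's own pre-stroke baseline (mean of days −7..−1). Two phase scores
summarize the outcome: the subacute deficit (mean of days 2–6, the dynamic
recovery phase) and the residual deficit (mean of days 12–21, the stable
phase, separated by a 5-day gap).

Three predictor sets are compared for each target:

* **lesion_volume** — edema-corrected lesion volume within the atlas, one
  scalar;
* **segmented_mri** — per-region lesion percentages over every atlas
  region lesioned in at least one animal;
* **subacute_deficit** — the measured subacute phase score (residual
  target only).

## Prediction error (PE)

The accuracy statistic is the repeated-split prediction error: the cohort
is split at random into training (2/3) and test (1/3) animals; a bagged
tree ensemble is fit on the training animals; the median absolute error of
the test predictions is recorded; this repeats over `n_models` independent
splits (default 50). PE is the mean of the per-split medians, in
percentage points of baseline performance. Reported Q1/Q3/IQR are means of
the per-split quartiles. All predictor sets for a target share identical
splits (enforced by a SHA-256 digest of the split indices), so comparisons
are paired.

## The forest

`OOBRandomForestRegressor` is a deliberately transparent bagged-tree
regressor: bootstrap samples are drawn outside the trees, so each tree's
out-of-bag (OOB) animals are known. That enables Breiman-style OOB
permutation importance — for each tree and feature, permute the feature
among the tree's OOB samples and record the rise in OOB mean squared
error, averaged over trees — which is the region-relevance statistic the
selection stage is built on. Individual trees are scikit-learn
`DecisionTreeRegressor`s.

Defaults: 500 trees, `max_features = ceil(p/3)`, `min_samples_leaf = 2`,
unlimited depth. The leaf size of 2 (rather than the more common 5) fits
the steep saturating dose-response between regional damage and deficit
measurably better (~0.5 pp PE on synthetic cohorts); both are exposed as
parameters.

## Region selection

Importance scores are averaged over the `n_models` split fits, reducing
dependence on any single bootstrap. Regions with score > 0 form the
positive-importance subset. The incremental-inclusion curve then
re-evaluates PE using the top-k regions for k = 1..K, on the same splits.
k\* is the first local minimum: the smallest interior k with
PE(k) ≤ PE(k−1) and PE(k) < PE(k+1); a plateau resolves to its smallest
interior k; endpoints are not minima (a monotone-decreasing curve reports
K, flagged).

Curve models deliberately differ from the comparison models in two ways
(`selection_max_features=None`, `selection_min_samples_leaf=8`):
with `max_features = ceil(k/3)`, the fraction of relevant features a
split may consider *drops* between adjacent k inside each ceiling stair
(1-of-3 at k=3 vs 1-of-2 at k=2), which manufactures spurious early local
minima in a curve whose whole point is comparing nested feature sets.
Using all features per split removes the artifact, and the larger leaves
damp greedy-split variance. These are evaluation-design choices, not
claims about the best predictive model.

## Behavior scoring

Raw records are long-format rows (animal, day, side, retrieved,
presented). Missing days are skipped, never imputed; an animal needs at
least one valid day per phase and a positive baseline. Performance may
exceed 100 % of baseline; only the deficit is floored at 0. Severity
grades 0–4 follow a modified-Rankin-style binning of percent-of-baseline
performance: ≥80 → 0, [60, 80) → 1, [40, 60) → 2, [20, 40) → 3, <20 → 4.
The paretic side comes from the covariates (right paw after left MCAO),
never inferred from the data. The subacute→residual grade transition
matrix (the numeric content of a recovery chord diagram) is produced as a
5×5 count table.

## Lesion quantification

All imaging operations work in 0-based voxel-index space on a shared grid;
masks must be pre-registered to the atlas (no resampling). Percentages use
exact integer voxel counts: pct_r = 100·|lesion ∩ r|/|r|. In-atlas lesion
volume counts only voxels with a nonzero label. Edema correction follows
the hemisphere-ratio strategy (corrected = raw × contralateral/ipsilateral
foreground volume), with the ipsilateral side chosen by lesion majority
and an exact midline tie broken to a configured side with a warning;
`edema_correction="none"` disables it. The heterogeneity statistic is the
relative deviation from the group mean, d_i = 100·|v_i − v̄|/v̄.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions every Monte-Carlo property test runs under.

**Atlas.** A mirror-symmetric ellipsoidal brain on a 40×32×32 grid of
0.2 mm voxels, split at the midline into hemispheres of 30 regions each:
a deep "core" compartment (striatum-like, surface distance ≥ 45 % of
maximum) and a superficial "shell" (cortex-like), each partitioned into
Lloyd-relaxed Voronoi regions (10 core, 20 shell per hemisphere), so
region volumes are roughly balanced.

**Lesions.** Each lesion grows by best-first connected accretion from a
deterministic striatal nucleation point, annexing the cheapest frontier
voxel until a target volume is reached. The cost field is Euclidean
distance + a shell penalty (1.2 mm, lognormal per-animal jitter, SD 1.4 on
the log scale) + a smooth random field (0.5 mm) + an iid per-region
vulnerability offset (2.6 mm, emulating collateral-flow variation between
territories). The target volume is latent severity × an occlusion-time
fraction of the hemisphere (30/45/60 min → 22/42/60 %) × lognormal noise
whose relative SD shrinks with occlusion time (0.85/0.35/0.22) — longer
occlusions give larger but more homogeneous infarcts, the direction seen
in incidence-map studies. The shell penalty makes cortex reachable only at
larger volumes (nested core-then-cortex topology); the region offsets make
*which* shell regions are involved partly independent of volume, which is
exactly why topology out-predicts volume downstream.

**Deficit link.** The acute deficit is a floor-anchored logistic of
normalized weighted damage u = Σ w_r·pct_r/100 / Σ w_r over 14 informative
regions (default: the 14 smallest shell regions of the lesioned
hemisphere, equal weights): zero damage maps exactly to zero deficit (sham
animals obey the same link), full damage saturates at 0.97. Midpoint 0.15
and scale 0.08 put typical cohorts on the responsive part of the curve.
Acute noise SD 0.035.

**Recovery.** Most animals recover toward acute·(0.40 + 0.25·acute) (mild
deficits recover proportionally more), with residual noise SD 0.02. With
probability 0.35·acute², an animal does not recover: it follows the same
early trajectory but relaxes back to its acute level after day 6
(secondary deterioration). Because the branch is invisible during the
subacute window, severe outcomes are intrinsically ambiguous at prediction
time — the mechanism behind the empirical rule that severe residual
deficits are the hardest to predict. The deficit trajectory relaxes
exponentially (rate 0.22/day) from the acute level at day 1; daily scores
are binomial draws of 20 pellets per side around the trajectory with 4 %
daily multiplicative noise. The non-paretic paw gets a smaller
(0.55×), fully transient dip. Training days −21..−1 ramp to an
animal-specific plateau (Normal(65, 8) %, clipped).

**Covariates.** Default cohort: 215 MCAO + 15 sham animals, 15 genotypes
(multiplicative volume factor, lognormal SD 0.15), 2 surgeons (the second
adds 3 mm³), occlusion 45 min, severity ~ Beta(3.5, 1.2). All randomness
derives from one master seed via per-animal `SeedSequence` streams, so
cohorts are bit-reproducible and stable under partial regeneration.

## What the synthetic tests show — and what they don't

Passing the property suite shows the *pipeline* is correct and that the
method recovers known structure: exact voxel arithmetic, paired PE
comparisons, the predictor ordering (subacute < segmented MRI < volume for
the residual target), recovery of the informative-region set, an
inclusion-curve minimum near the true region count, null safety, and the
heterogeneity direction. It does not show that real mouse cohorts have
this structure — the generator encodes the qualitative regularities of
the real study as assumptions (nested topology, saturating link,
recoveree/non-recoveree mixture), so the tests are parameter-recovery
checks, not replications. Real T2w intensities, registration error,
mortality/exclusion, and surgeon-by-study confounding are deliberately
absent.

## Problem sizes used in tests

Monte-Carlo properties run on 20 replicate cohorts. The predictor
comparison uses the default cohort (n=215 MCAO) with 30 splits × 100
trees; region selection uses dedicated n=500 cohorts (resolving the
marginal value of the 10th–14th region needs tighter per-split medians
than whole-predictor comparisons) with 20 splits × 70 trees for the
ranking and 22 × 60 for the curve (K=16); the heterogeneity direction uses
100 replicate pairs of 30-animal groups on a reduced 20-region atlas. The
full default pipeline (n=215, 50 splits, 500 trees) is what
`strokecast run` executes; the reduced schemes are unbiased versions of it
chosen so the whole suite runs on one CPU in tens of minutes.

## Known limitations

* The inclusion-curve minimum k\* is a noisy statistic: adjacent-k PE
  differences near the minimum are of the same order as evaluation noise,
  so k\* can land a few positions early on an unlucky cohort even with the
  variance controls above. The curve itself is stable; the argmin is not.
* The generator's lesion model is geometric, not hemodynamic; occlusion
  fractions and jitters are calibrated to qualitative directions
  (volume ordering, heterogeneity ordering, nesting), not to real-cohort
  magnitudes.
* Edema correction implements the hemisphere-ratio strategy only.
* Regions are a single ontology level; no hierarchical aggregation.
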