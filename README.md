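# strokecast

Prediction of post-stroke motor outcome in mice from early, non-invasive
measurements: atlas-segmented MRI lesion topography and the subacute
behavioral deficit.

## The problem

In the transient middle-cerebral-artery occlusion (MCAO) mouse model,
functional outcome after stroke is highly heterogeneous — across occlusion
times, genotypes and surgeons — and mice recover so strongly that
long-term deficits are hard to measure, let alone predict. Yet preclinical
intervention studies need exactly that prediction: to stratify animals, to
compare achieved with expected outcomes, and to decide treatments while
the therapeutic window is open. `strokecast` implements a complete,
reproducible pipeline for this problem, for experimental stroke
researchers and methods developers:

1. **Lesion quantification** — per-region lesion percentages over an atlas
   ("segmented MRI"), in-atlas lesion volume with hemisphere-ratio edema
   correction, cohort incidence maps, and the relative
   deviation-from-group-mean heterogeneity statistic.
2. **Behavior scoring** — staircase skilled-reaching records normalized to
   each animal's pre-stroke baseline (days −7..−1), summarized into a
   subacute (days 2–6) and a residual (days 12–21) phase score, graded on
   a 5-level modified-Rankin-style scale, with the subacute→residual
   transition matrix.
3. **Outcome prediction** — bagged regression trees evaluated over
   repeated 2/3–1/3 train/test splits. The accuracy statistic is the
   prediction error PE = mean over splits of the test-set median absolute
   error (percentage points of baseline). All predictor sets share
   identical splits, so comparisons are paired.
4. **Region selection** — out-of-bag permutation importance per atlas
   region, averaged over the split models; an incremental-inclusion PE
   curve over the top-k regions; and its first local minimum k\*, the
   number of regions that suffices for the prediction.
5. **Synthetic cohorts** — a generator producing toy atlases, stochastic
   nested (striatal-core / cortical-shell) lesion masks, covariates and
   behavioral time series with known ground truth, so the whole pipeline
   is testable end-to-end without animal data.

The scientific signature the pipeline is designed to detect (and, on
synthetic data, provably recovers): the residual deficit is predicted best
by the subacute deficit, then by lesion topology, then by plain lesion
volume; a small set of regions carries most of the topographic signal;
severe residual deficits are the hardest to predict; and shorter occlusion
times give smaller but relatively more variable lesions.

## Worked example

Simulate a small cohort and run the full pipeline:

```bash
strokecast simulate --seed 7 --n-animals 60 --out demo/cohort
strokecast run --config demo/config.yaml
```

with `demo/config.yaml`:

```yaml
atlas_labels: demo/cohort/atlas_labels.nii.gz
ontology: demo/cohort/ontology.csv
masks_dir: demo/cohort/masks
behavior_csv: demo/cohort/behavior.csv
covariates_csv: demo/cohort/covariates.csv
output_dir: demo/out
n_models: 50
n_estimators: 300
k_max: 16
master_seed: 7
```

The run prints (log excerpt):

```
INFO:strokecast:quantified 75 masks over 60 regions
INFO:strokecast:PE(lesion_volume -> residual) = 17.09 pp
INFO:strokecast:PE(segmented_mri -> residual) = 15.90 pp
INFO:strokecast:PE(subacute_deficit -> residual) = 12.67 pp
```

and `demo/out/report.md` summarizes:

```
## Prediction error (residual deficit, pp of baseline)

- subacute_deficit: 12.67
- segmented_mri: 15.90
- lesion_volume: 17.09

## Region selection

- positive-importance regions: 21
- first local minimum of inclusion curve: k* = 8
```

Reading: predicting an animal's stable (days 12–21) performance from its
early (days 2–6) performance is off by ~13 percentage points of baseline
in the median; using the day-1 MRI instead costs ~3 pp more, but the
region-resolved image beats the single volume number by ~1 pp, and on this
small 60-animal cohort ~8 regions carry the topographic signal (the
region-count estimate tightens on larger cohorts). `demo/out/` also contains the
per-region percentage matrix, the deficit summaries and transition matrix,
the importance ranking, the inclusion curve, and a `report.json` stamped
with the config hash, seed and package version (reruns are byte-identical).

Every stage is also a library call (`quantify_cohort`, `DeficitScorer`,
`RepeatedSplitForest`, `oob_importance`, `incremental_inclusion`,
`simulate_cohort`, ...) and a separate CLI subcommand
(`quantify`, `score-behavior`, `predict`, `select-regions`).

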