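"""End-to-end orchestration: quantify -> score -> predict -> select regions.

A :class:`PipelineConfig` (YAML/JSON-loadable) names the input files and all
stage parameters; :func:`run_pipeline` executes the stages and writes a
report directory whose every artifact carries the config hash, master seed
and package version. Reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AtlasVolume, load_atlas
from .behavior import DeficitScorer, transition_matrix
from .predict import (
    RepeatedSplitForest,
    SplitScheme,
    compare_predictors,
    incremental_inclusion,
    oob_importance,
    stratified_pe,
)
from .topography import LesionMask, RegionFilter, deviation_from_group_mean, incidence_map, quantify_cohort

log = logging.getLogger("strokecast")

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Structured pipeline failure naming the stage and animals involved."""

    def __init__(self, stage: str, message: str, animal_ids: list[str] | None = None):
        self.stage = stage
        self.animal_ids = animal_ids or []
        suffix = f" (animals: {', '.join(self.animal_ids)})" if self.animal_ids else ""
        super().__init__(f"[{stage}] {message}{suffix}")


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run."""

    atlas_labels: str
    ontology: str
    masks_dir: str
    behavior_csv: str
    covariates_csv: str
    output_dir: str
    cohort_role: str = "prediction"            # prediction | replication
    master_seed: int = 0
    # behavior scoring
    baseline_window: tuple[int, int] = (-7, -1)
    subacute_window: tuple[int, int] = (2, 6)
    residual_window: tuple[int, int] = (12, 21)
    grade_thresholds: tuple[float, ...] = (80.0, 60.0, 40.0, 20.0)
    # lesion quantification
    edema_correction: str = "hemisphere_ratio"
    # prediction
    n_models: int = 50
    train_fraction: float = 2.0 / 3.0
    n_estimators: int = 500
    max_features: str | int | float = "third"
    min_samples_leaf: int = 2
    max_depth: int | None = None
    target: str = "residual"                   # residual | subacute
    # region selection: the inclusion curve compares nested feature sets, so
    # its models use all features per split (no subsampling stair-steps
    # between adjacent k) and stronger leaf smoothing
    k_max: int = 20
    selection_n_models: int = 25
    selection_n_estimators: int = 80
    selection_max_features: str | int | float | None = None
    selection_min_samples_leaf: int = 8

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("baseline_window", "subacute_window", "residual_window"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        cfg.grade_thresholds = tuple(cfg.grade_thresholds)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    def content_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir")  # where results land does not change what they are
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "config_hash": config.content_hash(),
        "master_seed": config.master_seed,
        "package_version": __version__,
    }


def _load_inputs(config: PipelineConfig):
    atlas = load_atlas(config.atlas_labels, config.ontology)
    covariates = pd.read_csv(config.covariates_csv).set_index("animal_id")
    behavior = pd.read_csv(config.behavior_csv)
    masks = []
    missing = []
    masks_dir = Path(config.masks_dir)
    for animal in covariates.index:
        path = masks_dir / f"{animal}.nii.gz"
        if not path.exists():
            missing.append(str(animal))
            continue
        masks.append(LesionMask.from_nifti(path, str(animal)))
    if missing:
        raise PipelineError("load", "missing lesion mask file(s)", missing)
    return atlas, covariates, behavior, masks


def run_pipeline(config: PipelineConfig) -> Path:
    """Run quantify -> score -> predict -> select-regions -> report.

    Returns the output directory. Only MCAO animals (covariates group ==
    'mcao') enter the prediction stages; sham animals are still quantified
    and scored.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    prov = _provenance(config)

    atlas, covariates, behavior, masks = _load_inputs(config)

    # ---- quantify
    try:
        pct, vols = quantify_cohort(masks, atlas, edema_correction=config.edema_correction)
    except ValueError as err:
        raise PipelineError("quantify", str(err)) from err
    pct.to_csv(out / "region_percentages.csv")
    vols.to_csv(out / "volumes.csv")
    imap = incidence_map(masks)
    imap.to_nifti(out / "incidence_map.nii.gz", atlas)
    log.info("quantified %d masks over %d regions", len(masks), pct.shape[1])

    # ---- score behavior
    scorer = DeficitScorer(
        baseline_window=config.baseline_window,
        subacute_window=config.subacute_window,
        residual_window=config.residual_window,
        grade_thresholds=config.grade_thresholds,
    )
    paretic = covariates["paretic_side"].to_dict()
    summary = scorer.score(behavior, paretic)
    summary.to_csv(out / "deficit_summary.csv")
    trans = transition_matrix(summary.dropna(subset=["subacute_grade", "residual_grade"]))
    trans.to_csv(out / "transition_matrix.csv")

    # ---- assemble predictor sets (MCAO animals with complete scores)
    mcao_ids = [a for a in covariates.index[covariates["group"] == "mcao"] if a in summary.index]
    if len(mcao_ids) < 6:
        raise PipelineError("predict", f"only {len(mcao_ids)} scorable MCAO animals")
    X_pct = pct.loc[mcao_ids]
    region_filter = RegionFilter().fit(X_pct)
    X_seg = region_filter.transform(X_pct)
    pd.Series(region_filter.kept_regions_, name="region_id").to_csv(
        out / "kept_regions.csv", index=False
    )
    y_sub = summary.loc[mcao_ids, "subacute_pct_paretic"].to_numpy()
    y_res = summary.loc[mcao_ids, "residual_pct_paretic"].to_numpy()
    target = {"residual": y_res, "subacute": y_sub}[config.target]

    scheme = SplitScheme(
        n_models=config.n_models,
        train_fraction=config.train_fraction,
        master_seed=config.master_seed,
    )

    def make_evaluator(n_models=None, n_estimators=None, seed_offset=0):
        return RepeatedSplitForest(
            scheme=SplitScheme(
                n_models=n_models or scheme.n_models,
                train_fraction=scheme.train_fraction,
                master_seed=scheme.master_seed + seed_offset,
            ),
            n_estimators=n_estimators or config.n_estimators,
            max_features=config.max_features,
            min_samples_leaf=config.min_samples_leaf,
            max_depth=config.max_depth,
        )

    predictor_sets = {
        "lesion_volume": vols.loc[mcao_ids, ["corrected_volume_mm3"]].to_numpy(),
        "segmented_mri": X_seg.to_numpy(),
    }
    if config.target == "residual":
        predictor_sets["subacute_deficit"] = y_sub[:, None]

    reports = {}
    seg_evaluator = None
    for name, X in predictor_sets.items():
        ev = make_evaluator()
        reports[name] = ev.evaluate(X, target, predictor=name, target=config.target)
        if name == "segmented_mri":
            seg_evaluator = ev
        log.info("PE(%s -> %s) = %.2f pp", name, config.target, reports[name].pe)
    comparison = compare_predictors(list(reports.values()))
    comparison.to_csv(out / "predictor_comparison.csv")

    grades = summary.loc[mcao_ids, f"{config.target}_grade"].to_numpy()
    strat = pd.DataFrame(
        {name: stratified_pe(rep, grades) for name, rep in reports.items()}
    )
    strat.to_csv(out / "stratified_pe.csv")

    # ---- importance + incremental inclusion (residual target only)
    selection = None
    if config.target == "residual":
        ranking = oob_importance(X_seg, target, make_evaluator())
        ranking.scores.rename("importance").to_csv(out / "importance_ranking.csv")
        ev_sel = RepeatedSplitForest(
            scheme=SplitScheme(
                n_models=config.selection_n_models,
                train_fraction=scheme.train_fraction,
                master_seed=scheme.master_seed + 7919,
            ),
            n_estimators=config.selection_n_estimators,
            max_features=config.selection_max_features,
            min_samples_leaf=config.selection_min_samples_leaf,
            max_depth=config.max_depth,
        )
        curve = incremental_inclusion(
            ranking, X_seg, target, ev_sel, k_max=min(config.k_max, X_seg.shape[1])
        )
        curve.curve.to_csv(out / "inclusion_curve.csv", index=False)
        selection = {
            "k_star": int(curve.k_star),
            "interior_minimum": bool(curve.interior_minimum),
            "n_positive_importance": len(ranking.positive_regions),
            "regions_in_order": curve.regions_in_order,
        }

    # ---- heterogeneity summary
    occ_dev = {}
    for occ, group in covariates.loc[mcao_ids].groupby("occlusion_minutes"):
        v = vols.loc[group.index, "corrected_volume_mm3"]
        if v.mean() > 0:
            occ_dev[int(occ)] = float(np.mean(deviation_from_group_mean(v)))

    report = {
        **prov,
        "cohort_role": config.cohort_role,
        "n_animals": int(len(covariates)),
        "n_mcao_scored": len(mcao_ids),
        "n_kept_regions": len(region_filter.kept_regions_),
        "target": config.target,
        "prediction_error_pp": {k: round(r.pe, 4) for k, r in reports.items()},
        "reports": {k: r.to_dict() for k, r in reports.items()},
        "stratified_pe": json.loads(strat.to_json()),
        "transition_matrix": trans.values.tolist(),
        "mean_deviation_from_group_mean_pct": occ_dev,
        "region_selection": selection,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    _write_markdown_summary(report, out / "report.md")
    log.info("pipeline complete: %s", out)
    return out


def _write_markdown_summary(report: dict, path: Path) -> None:
    lines = [
        "# strokecast report",
        "",
        f"- config hash: `{report['config_hash']}`, seed {report['master_seed']}, "
        f"version {report['package_version']}",
        f"- cohort: {report['cohort_role']}, {report['n_mcao_scored']} scored MCAO animals "
        f"of {report['n_animals']} total, {report['n_kept_regions']} kept regions",
        "",
        f"## Prediction error ({report['target']} deficit, pp of baseline)",
        "",
    ]
    for name, pe in sorted(report["prediction_error_pp"].items(), key=lambda kv: kv[1]):
        lines.append(f"- {name}: {pe:.2f}")
    sel = report.get("region_selection")
    if sel:
        lines += [
            "",
            "## Region selection",
            "",
            f"- positive-importance regions: {sel['n_positive_importance']}",
            f"- first local minimum of inclusion curve: k* = {sel['k_star']}"
            + ("" if sel["interior_minimum"] else " (no interior minimum; last k)"),
        ]
    path.write_text("\n".join(lines) + "\n")
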