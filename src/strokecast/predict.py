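"""Repeated-split outcome prediction and importance-driven region selection.

The accuracy statistic throughout is the prediction error (PE): the cohort
is split into training (two-thirds) and test (one-third) animals; a bagged
tree ensemble is fit on the training animals; the median absolute error on
the test animals is recorded; and the whole procedure is repeated over
``n_models`` (default 50) independent random splits. PE is the mean of the
per-split median absolute errors, in percentage points of baseline
performance. Reported quartiles and IQR are likewise means of the
per-split quartiles.

All predictor sets for a given target share the identical splits (asserted
via a split hash), so predictor comparisons are paired. Region selection
ranks atlas regions by OOB permutation importance averaged over the split
models, then re-evaluates PE with an increasing number of top regions and
reports the first local minimum of that inclusion curve.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .forest import OOBRandomForestRegressor

__all__ = [
    "SplitScheme",
    "PredictionReport",
    "ImportanceRanking",
    "InclusionCurve",
    "make_splits",
    "fit_predict_once",
    "prediction_error",
    "RepeatedSplitForest",
    "compare_predictors",
    "oob_importance",
    "incremental_inclusion",
    "importance_from_models",
    "first_local_minimum",
    "stratified_pe",
    "validate_on_cohort",
]


@dataclass(frozen=True)
class SplitScheme:
    """Repeated random train/test partitions (no stratification)."""

    n_models: int = 50
    train_fraction: float = 2.0 / 3.0
    master_seed: int = 0

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def _split_seed(master_seed: int, model_index: int) -> int:
    """Stable per-model seed derived from (master_seed, model index)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(model_index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def make_splits(n_animals: int, scheme: SplitScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent uniform random train/test partitions.

    Test size is round(n * (1 - train_fraction)); each split is a disjoint
    partition of all animals, reproducible from the scheme's master seed.
    """
    if n_animals < 6:
        raise ValueError("need at least 6 animals to split")
    n_test = int(round(n_animals * (1.0 - scheme.train_fraction)))
    n_test = min(max(n_test, 1), n_animals - 1)
    splits = []
    for m in range(scheme.n_models):
        rng = np.random.default_rng(_split_seed(scheme.master_seed, m))
        perm = rng.permutation(n_animals)
        splits.append((np.sort(perm[n_test:]), np.sort(perm[:n_test])))
    return splits


def splits_hash(splits: Sequence[tuple[np.ndarray, np.ndarray]]) -> str:
    """Digest of a split list; equal digests guarantee paired comparisons."""
    h = hashlib.sha256()
    for train, test in splits:
        h.update(np.asarray(train, dtype=np.int64).tobytes())
        h.update(b"|")
        h.update(np.asarray(test, dtype=np.int64).tobytes())
        h.update(b";")
    return h.hexdigest()


def fit_predict_once(
    X: np.ndarray,
    y: np.ndarray,
    split: tuple[np.ndarray, np.ndarray],
    seed: int,
    **forest_params,
) -> np.ndarray:
    """Fit one bagged-forest model on the train rows; return test |error|s."""
    train, test = split
    model = OOBRandomForestRegressor(random_state=seed, **forest_params)
    model.fit(X[train], y[train])
    return np.abs(model.predict(X[test]) - y[test])


def prediction_error(per_model_errors: Sequence[np.ndarray]) -> dict:
    """PE with averaged quartiles from per-split absolute-error lists.

    Per split: median, Q1, Q3 of the test absolute errors. PE is the mean
    of the medians; reported Q1/Q3/IQR are means of the per-split values.
    """
    if len(per_model_errors) == 0:
        raise ValueError("need at least one model's errors")
    medians, q1s, q3s = [], [], []
    for errs in per_model_errors:
        errs = np.asarray(errs, dtype=float)
        if errs.size == 0:
            raise ValueError("a model has an empty error list")
        medians.append(np.median(errs))
        q1s.append(np.percentile(errs, 25))
        q3s.append(np.percentile(errs, 75))
    q1, q3 = float(np.mean(q1s)), float(np.mean(q3s))
    return {
        "pe": float(np.mean(medians)),
        "q1": q1,
        "q3": q3,
        "iqr": q3 - q1,
        "per_model_medians": [float(m) for m in medians],
    }


@dataclass
class PredictionReport:
    """Accuracy of one predictor set for one target over repeated splits."""

    predictor: str
    target: str
    pe: float
    q1: float
    q3: float
    iqr: float
    per_model_medians: list[float]
    per_model_errors: list[np.ndarray]
    per_model_test_indices: list[np.ndarray]
    n_animals: int
    scheme: SplitScheme
    split_hash: str
    seeds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "target": self.target,
            "pe": self.pe,
            "q1": self.q1,
            "q3": self.q3,
            "iqr": self.iqr,
            "per_model_medians": self.per_model_medians,
            "n_animals": self.n_animals,
            "n_models": self.scheme.n_models,
            "train_fraction": self.scheme.train_fraction,
            "master_seed": self.scheme.master_seed,
            "split_hash": self.split_hash,
            "seeds": self.seeds,
        }


class RepeatedSplitForest:
    """Repeated-split bagged-forest evaluator (the PE machine).

    ``evaluate(X, y)`` runs the full split scheme and returns a
    :class:`PredictionReport`; ``fit``/``predict`` expose the ensemble of
    split models as a single regressor (mean over models), so the object
    also behaves like an estimator for transfer-style validation.
    """

    def __init__(
        self,
        scheme: SplitScheme = SplitScheme(),
        n_estimators: int = 500,
        max_features="third",
        min_samples_leaf: int = 2,
        max_depth: int | None = None,
        compute_oob: bool = True,
    ):
        self.scheme = scheme
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.compute_oob = compute_oob

    def _forest_params(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "max_features": self.max_features,
            "min_samples_leaf": self.min_samples_leaf,
            "max_depth": self.max_depth,
            "compute_oob": self.compute_oob,
        }

    def fit(self, X, y, predictor: str = "predictor", target: str = "target") -> "RepeatedSplitForest":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        splits = make_splits(n, self.scheme)
        self.splits_ = splits
        self.split_hash_ = splits_hash(splits)
        self.models_ = []
        seeds, errors, test_indices = [], [], []
        for m, (train, test) in enumerate(splits):
            seed = _split_seed(self.scheme.master_seed, m) ^ 0x5F5F5F
            model = OOBRandomForestRegressor(random_state=seed, **self._forest_params())
            model.fit(X[train], y[train])
            self.models_.append(model)
            errs = np.abs(model.predict(X[test]) - y[test])
            errors.append(errs)
            test_indices.append(test)
            seeds.append(seed)
        stats = prediction_error(errors)
        self.report_ = PredictionReport(
            predictor=predictor,
            target=target,
            pe=stats["pe"],
            q1=stats["q1"],
            q3=stats["q3"],
            iqr=stats["iqr"],
            per_model_medians=stats["per_model_medians"],
            per_model_errors=errors,
            per_model_test_indices=test_indices,
            n_animals=n,
            scheme=self.scheme,
            split_hash=self.split_hash_,
            seeds=seeds,
        )
        return self

    def evaluate(self, X, y, predictor: str = "predictor", target: str = "target") -> PredictionReport:
        self.fit(X, y, predictor=predictor, target=target)
        return self.report_

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = np.zeros(X.shape[0])
        for model in self.models_:
            out += model.predict(X)
        return out / len(self.models_)


def compare_predictors(reports: Sequence[PredictionReport]) -> pd.DataFrame:
    """Ordered comparison table of PE across predictor sets on shared splits.

    Requires identical split schemes (checked via the split hash) so the
    pairwise PE differences are paired across the per-model medians.
    Returns one row per predictor, ascending PE, with averaged quartiles
    and a diff_vs_best column (mean paired difference of per-model medians
    against the best predictor).
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    h0, t0 = reports[0].split_hash, reports[0].target
    for r in reports[1:]:
        if r.split_hash != h0:
            raise ValueError("reports use different splits; comparison would be unpaired")
        if r.target != t0:
            raise ValueError("reports target different outcomes")
    rows = sorted(reports, key=lambda r: r.pe)
    best = np.asarray(rows[0].per_model_medians)
    table = pd.DataFrame(
        {
            "predictor": [r.predictor for r in rows],
            "pe": [r.pe for r in rows],
            "q1": [r.q1 for r in rows],
            "q3": [r.q3 for r in rows],
            "iqr": [r.iqr for r in rows],
            "diff_vs_best": [
                float(np.mean(np.asarray(r.per_model_medians) - best)) for r in rows
            ],
        }
    ).set_index("predictor")
    return table


@dataclass
class ImportanceRanking:
    """Per-region OOB permutation importance, averaged over split models."""

    scores: pd.Series                    # region_id -> importance, descending
    positive_regions: list[int]          # score > 0, in ranking order

    @property
    def ranked_ids(self) -> list[int]:
        return [int(r) for r in self.scores.index]


def _rank_scores(scores: pd.Series) -> pd.Series:
    """Sort descending by score, ties broken by ascending region id."""
    frame = scores.rename("score").reset_index()
    frame.columns = ["region_id", "score"]
    frame = frame.sort_values(["score", "region_id"], ascending=[False, True])
    return frame.set_index("region_id")["score"]


def importance_from_models(
    evaluator: RepeatedSplitForest, feature_names: Sequence
) -> ImportanceRanking:
    """OOB permutation importance averaged over an evaluator's fitted models.

    Averaging across the ``n_models`` split fits reduces the dependence on
    any single bootstrap. The positive subset (score > 0) is the set of
    regions that beat permuted (random) data.
    """
    if not hasattr(evaluator, "models_"):
        raise ValueError("evaluator must be fitted first")
    p = len(feature_names)
    total = np.zeros(p)
    for model, seed in zip(evaluator.models_, evaluator.report_.seeds):
        total += model.oob_permutation_importance(random_state=seed ^ 0xA5A5)
    scores = pd.Series(total / len(evaluator.models_), index=list(feature_names))
    ranked = _rank_scores(scores)
    positive = [int(r) for r in ranked.index[ranked > 0]]
    return ImportanceRanking(scores=ranked, positive_regions=positive)


def oob_importance(
    X: pd.DataFrame,
    y: np.ndarray,
    evaluator: RepeatedSplitForest,
) -> ImportanceRanking:
    """Region importance from OOB permutation over the repeated-split models.

    Fits the evaluator's split scheme on the region-percentage matrix, then
    averages each model's per-tree OOB permutation importance across fits.
    """
    evaluator.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=float),
                  predictor="segmented_mri", target="importance")
    return importance_from_models(evaluator, X.columns)


def first_local_minimum(pe: Sequence[float]) -> tuple[int, bool]:
    """First local minimum of an inclusion curve (1-based k).

    Returns (k_star, interior): the smallest interior k with
    PE(k) <= PE(k-1) and PE(k) < PE(k+1); a plateau at the minimum resolves
    to its smallest k. Endpoints are not minima; if no interior minimum
    exists (e.g. a monotone decreasing curve), k_star is the last k and
    interior is False.
    """
    pe = np.asarray(pe, dtype=float)
    if pe.size < 3:
        return len(pe), False
    for i in range(1, pe.size - 1):
        if pe[i] <= pe[i - 1] and pe[i] < pe[i + 1]:
            # a plateau at the minimum resolves to its smallest interior k
            while i > 1 and pe[i - 1] == pe[i]:
                i -= 1
            return i + 1, True
    return int(pe.size), False


@dataclass
class InclusionCurve:
    """PE as a function of the number of included top-importance regions."""

    curve: pd.DataFrame      # columns: k, pe, q1, q3, iqr
    k_star: int
    interior_minimum: bool
    regions_in_order: list[int]


def incremental_inclusion(
    ranking: ImportanceRanking,
    X: pd.DataFrame,
    y: np.ndarray,
    evaluator: RepeatedSplitForest,
    k_max: int | None = None,
) -> InclusionCurve:
    """PE curve over models built from the top-k most important regions.

    Every k reuses the evaluator's split scheme, so the curve is internally
    paired; k runs from 1 to ``k_max`` (truncated with a warning if it
    exceeds the number of ranked regions).
    """
    import warnings

    ranked = ranking.ranked_ids
    if len(ranked) == 0:
        raise ValueError("ranking is empty")
    if k_max is None:
        k_max = len(ranked)
    if k_max > len(ranked):
        warnings.warn(
            f"k_max={k_max} exceeds the {len(ranked)} ranked regions; truncating",
            stacklevel=2,
        )
        k_max = len(ranked)
    y = np.asarray(y, dtype=float)
    rows = []
    for k in range(1, k_max + 1):
        cols = ranked[:k]
        rep = RepeatedSplitForest(
            scheme=evaluator.scheme,
            n_estimators=evaluator.n_estimators,
            max_features=evaluator.max_features,
            min_samples_leaf=evaluator.min_samples_leaf,
            max_depth=evaluator.max_depth,
            compute_oob=False,  # the curve needs test-split errors only
        ).evaluate(X[cols].to_numpy(dtype=float), y, predictor=f"top_{k}_regions", target="residual")
        rows.append({"k": k, "pe": rep.pe, "q1": rep.q1, "q3": rep.q3, "iqr": rep.iqr})
    curve = pd.DataFrame(rows)
    k_star, interior = first_local_minimum(curve["pe"].to_numpy())
    return InclusionCurve(curve=curve, k_star=k_star, interior_minimum=interior,
                          regions_in_order=[int(r) for r in ranked[:k_max]])


def stratified_pe(report: PredictionReport, grades: Sequence[int]) -> pd.Series:
    """PE per severity grade of the test animals.

    Within each split, the median absolute error is computed over test
    animals of each grade; the per-grade PE is the mean of those medians
    over the splits that contain the grade. Grades never seen in any test
    set are reported as NaN (missing, not zero).
    """
    grades = np.asarray(grades)
    per_grade_medians: dict[int, list[float]] = {}
    for errs, test in zip(report.per_model_errors, report.per_model_test_indices):
        g = grades[test]
        for grade in np.unique(g):
            per_grade_medians.setdefault(int(grade), []).append(
                float(np.median(np.asarray(errs)[g == grade]))
            )
    all_grades = sorted(set(int(g) for g in np.unique(grades)))
    out = pd.Series(
        {g: float(np.mean(per_grade_medians[g])) if g in per_grade_medians else np.nan
         for g in all_grades},
        name="pe",
    )
    out.index.name = "grade"
    return out


def validate_on_cohort(
    kept_regions: Sequence[int],
    X_repl: pd.DataFrame,
    y_repl: np.ndarray,
    evaluator: RepeatedSplitForest,
    mode: str = "refit",
    trained: RepeatedSplitForest | None = None,
    predictor: str = "segmented_mri",
    target: str = "residual",
) -> PredictionReport:
    """Evaluate the frozen pipeline on an independent replication cohort.

    The kept-region list and all hyperparameters are frozen from the
    prediction cohort. In ``refit`` mode (default) the split scheme is
    re-run within the replication cohort, matching per-cohort PE
    computation; in ``transfer`` mode the models trained on the prediction
    cohort predict the replication animals directly and the same repeated
    test splits are used for error summarization only.
    """
    missing = [r for r in kept_regions if r not in X_repl.columns]
    if missing:
        raise ValueError(f"replication cohort missing kept regions: {missing}")
    X = X_repl[list(kept_regions)].to_numpy(dtype=float)
    y = np.asarray(y_repl, dtype=float)
    if mode == "refit":
        rep = RepeatedSplitForest(
            scheme=evaluator.scheme,
            n_estimators=evaluator.n_estimators,
            max_features=evaluator.max_features,
            min_samples_leaf=evaluator.min_samples_leaf,
            max_depth=evaluator.max_depth,
        ).evaluate(X, y, predictor=predictor, target=target)
        return rep
    if mode == "transfer":
        if trained is None or not hasattr(trained, "models_"):
            raise ValueError("transfer mode needs a fitted evaluator from the prediction cohort")
        splits = make_splits(X.shape[0], evaluator.scheme)
        errors, tests = [], []
        abs_err = np.abs(trained.predict(X) - y)
        for train, test in splits:
            errors.append(abs_err[test])
            tests.append(test)
        stats = prediction_error(errors)
        return PredictionReport(
            predictor=predictor,
            target=target,
            pe=stats["pe"],
            q1=stats["q1"],
            q3=stats["q3"],
            iqr=stats["iqr"],
            per_model_medians=stats["per_model_medians"],
            per_model_errors=errors,
            per_model_test_indices=tests,
            n_animals=X.shape[0],
            scheme=evaluator.scheme,
            split_hash=splits_hash(splits),
            seeds=[],
        )
    raise ValueError(f"mode must be 'refit' or 'transfer', got {mode!r}")
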