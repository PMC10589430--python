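"""Staircase skilled-reaching scores: baselines, phases, grades, transitions.

Raw records are long-format rows (animal_id, day, side, pellets_retrieved,
pellets_presented). Performance is the percentage of pellets collected per
side; each animal/paw is normalized to its own pre-stroke baseline (mean of
days -7..-1), then summarized over a subacute window (days 2-6, dynamic
recovery) and a residual window (days 12-21, stable), with a 5-day gap so
the dynamic phase has ended. Severity grades 0-4 follow a modified-Rankin-
style binning of the deficit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "daily_performance",
    "baseline_normalize",
    "phase_mean",
    "severity_grade",
    "transition_matrix",
    "DeficitScorer",
    "DEFAULT_GRADE_THRESHOLDS",
]

#: performance thresholds (percent of baseline), strictly decreasing; grade =
#: number of these a deficit exceeds: >=80 -> 0, [60,80) -> 1, [40,60) -> 2,
#: [20,40) -> 3, <20 -> 4.
DEFAULT_GRADE_THRESHOLDS: tuple[float, ...] = (80.0, 60.0, 40.0, 20.0)

_REQUIRED = ("animal_id", "day", "side", "pellets_retrieved", "pellets_presented")


def _validate_record(record: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in record.columns]
    if missing:
        raise ValueError(f"behavior record missing columns: {missing}")
    if (record["pellets_presented"] <= 0).any():
        raise ValueError("pellets_presented must be positive")
    bad = record["pellets_retrieved"] > record["pellets_presented"]
    if bad.any():
        rows = record.loc[bad, ["animal_id", "day", "side"]].head()
        raise ValueError(f"pellets_retrieved > pellets_presented, e.g.:\n{rows}")
    if (record["pellets_retrieved"] < 0).any():
        raise ValueError("pellets_retrieved must be non-negative")
    return record


def daily_performance(record: pd.DataFrame) -> pd.DataFrame:
    """Percent of pellets retrieved per (animal, day, side).

    Missing days are simply absent from the output; they are never
    zero-filled.
    """
    record = _validate_record(record)
    out = record[["animal_id", "day", "side"]].copy()
    out["pct"] = 100.0 * record["pellets_retrieved"] / record["pellets_presented"]
    return out


def baseline_normalize(
    daily: pd.DataFrame,
    baseline_window: tuple[int, int] = (-7, -1),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Express each animal/side's performance in percent of its own baseline.

    The baseline is the mean raw performance over available days inside the
    closed window (default days -7..-1). Returns (normalized long frame
    with column pct_of_baseline, baseline table). Animal/sides with no
    baseline day or a zero baseline are flagged unusable and dropped from
    the normalized frame.
    """
    lo, hi = baseline_window
    base_rows = daily[(daily["day"] >= lo) & (daily["day"] <= hi)]
    baseline = (
        base_rows.groupby(["animal_id", "side"])["pct"]
        .agg(baseline_pct="mean", n_baseline_days="count")
        .reset_index()
    )
    baseline["usable"] = (baseline["n_baseline_days"] > 0) & (baseline["baseline_pct"] > 0)

    merged = daily.merge(
        baseline[["animal_id", "side", "baseline_pct", "usable"]],
        on=["animal_id", "side"],
        how="left",
    )
    merged["usable"] = merged["usable"].fillna(False)
    usable = merged[merged["usable"]].copy()
    usable["pct_of_baseline"] = 100.0 * usable["pct"] / usable["baseline_pct"]
    return (
        usable[["animal_id", "day", "side", "pct_of_baseline"]],
        baseline,
    )


def phase_mean(
    normalized: pd.DataFrame,
    window: tuple[int, int],
    value_col: str = "pct_of_baseline",
) -> pd.DataFrame:
    """Mean performance per animal/side over available days in a closed window.

    Animal/sides with no data inside the window are absent from the output
    (callers treat them as excluded, not zero).
    """
    lo, hi = window
    rows = normalized[(normalized["day"] >= lo) & (normalized["day"] <= hi)]
    return (
        rows.groupby(["animal_id", "side"])[value_col]
        .agg(phase_pct="mean", n_days_used="count")
        .reset_index()
    )


def severity_grade(
    phase_pct: float | np.ndarray,
    thresholds: Sequence[float] = DEFAULT_GRADE_THRESHOLDS,
) -> int | np.ndarray:
    """Ordinal severity grade 0 (no deficit) .. 4 (severe) from a phase mean.

    The deficit is 100 - phase_pct, floored at 0 (performance above
    baseline is not a negative deficit); the grade counts how many of the
    four deficit cut-offs it exceeds.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.size != 4 or not np.all(np.diff(t) < 0):
        raise ValueError(f"thresholds must be 4 strictly decreasing values, got {thresholds}")
    deficit = np.maximum(100.0 - np.asarray(phase_pct, dtype=float), 0.0)
    cut = 100.0 - t  # deficit cut-offs, ascending
    grade = (deficit[..., None] > cut).sum(axis=-1)
    return int(grade) if np.isscalar(phase_pct) else grade


def transition_matrix(summaries: pd.DataFrame, n_grades: int = 5) -> pd.DataFrame:
    """Counts of (subacute grade, residual grade) pairs across a cohort.

    Rows are subacute grades, columns residual grades; cell (i, j) counts
    animals whose subacute-phase grade i recovered (or not) to residual
    grade j — the numeric content of a recovery chord diagram.
    """
    for col in ("subacute_grade", "residual_grade"):
        if col not in summaries.columns:
            raise ValueError(f"summaries missing column {col!r}")
        if summaries[col].isna().any():
            raise ValueError(f"summaries contain missing {col!r}")
    counts = np.zeros((n_grades, n_grades), dtype=int)
    for s, r in zip(summaries["subacute_grade"], summaries["residual_grade"]):
        counts[int(s), int(r)] += 1
    return pd.DataFrame(
        counts,
        index=pd.Index(range(n_grades), name="subacute_grade"),
        columns=pd.Index(range(n_grades), name="residual_grade"),
    )


@dataclass
class _Windows:
    baseline: tuple[int, int]
    subacute: tuple[int, int]
    residual: tuple[int, int]


class DeficitScorer(BaseEstimator):
    """Turn raw staircase records into per-animal deficit summaries.

    Parameters follow the study design: baseline days -7..-1, subacute
    phase days 2-6, residual phase days 12-21, and the 20-point severity
    bins. The paretic side comes from the covariates, never from the data.
    """

    def __init__(
        self,
        baseline_window: tuple[int, int] = (-7, -1),
        subacute_window: tuple[int, int] = (2, 6),
        residual_window: tuple[int, int] = (12, 21),
        grade_thresholds: Sequence[float] = DEFAULT_GRADE_THRESHOLDS,
    ):
        self.baseline_window = baseline_window
        self.subacute_window = subacute_window
        self.residual_window = residual_window
        self.grade_thresholds = grade_thresholds

    def score(
        self,
        record: pd.DataFrame,
        paretic_side: Mapping[str, str] | str,
    ) -> pd.DataFrame:
        """Compute per-animal summaries (one row per animal).

        ``paretic_side`` is either a single side for the whole cohort or a
        mapping animal_id -> side. Output columns: baseline/subacute/
        residual pct per side (columns suffixed _paretic/_nonparetic),
        n_days per phase, and subacute_grade / residual_grade computed on
        the paretic paw. Animals lacking a usable baseline or any phase day
        on the paretic paw are dropped.
        """
        daily = daily_performance(record)
        normalized, baseline = baseline_normalize(daily, self.baseline_window)
        sub = phase_mean(normalized, self.subacute_window).rename(
            columns={"phase_pct": "subacute_pct", "n_days_used": "n_days_subacute"}
        )
        res = phase_mean(normalized, self.residual_window).rename(
            columns={"phase_pct": "residual_pct", "n_days_used": "n_days_residual"}
        )
        merged = baseline[baseline["usable"]][
            ["animal_id", "side", "baseline_pct"]
        ].merge(sub, on=["animal_id", "side"], how="inner").merge(
            res, on=["animal_id", "side"], how="inner"
        )

        if isinstance(paretic_side, str):
            merged["is_paretic"] = merged["side"] == paretic_side
        else:
            merged["is_paretic"] = [
                s == paretic_side.get(a) for a, s in zip(merged["animal_id"], merged["side"])
            ]

        paretic = merged[merged["is_paretic"]].copy()
        nonpar = merged[~merged["is_paretic"]].copy()
        out = paretic.set_index("animal_id")[
            ["baseline_pct", "subacute_pct", "residual_pct", "n_days_subacute", "n_days_residual"]
        ].rename(
            columns={
                "baseline_pct": "baseline_pct_paretic",
                "subacute_pct": "subacute_pct_paretic",
                "residual_pct": "residual_pct_paretic",
            }
        )
        np_cols = nonpar.set_index("animal_id")[
            ["baseline_pct", "subacute_pct", "residual_pct"]
        ].rename(
            columns={
                "baseline_pct": "baseline_pct_nonparetic",
                "subacute_pct": "subacute_pct_nonparetic",
                "residual_pct": "residual_pct_nonparetic",
            }
        )
        out = out.join(np_cols, how="left")
        out["subacute_grade"] = severity_grade(
            out["subacute_pct_paretic"].to_numpy(), self.grade_thresholds
        )
        out["residual_grade"] = severity_grade(
            out["residual_pct_paretic"].to_numpy(), self.grade_thresholds
        )
        out.index.name = "animal_id"
        return out
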