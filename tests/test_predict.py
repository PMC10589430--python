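"""Repeated-split PE machinery, importance ranking, inclusion curve."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokecast import (
    RepeatedSplitForest,
    SplitScheme,
    compare_predictors,
    first_local_minimum,
    incremental_inclusion,
    make_splits,
    oob_importance,
    prediction_error,
    stratified_pe,
    validate_on_cohort,
)
from strokecast.predict import splits_hash


class TestSplits:
    def test_two_thirds_one_third(self):
        splits = make_splits(9, SplitScheme(n_models=10, master_seed=0))
        for train, test in splits:
            assert len(train) == 6 and len(test) == 3

    def test_reproducible(self):
        a = make_splits(30, SplitScheme(n_models=5, master_seed=3))
        b = make_splits(30, SplitScheme(n_models=5, master_seed=3))
        assert splits_hash(a) == splits_hash(b)

    @given(st.integers(min_value=6, max_value=80), st.integers(min_value=0, max_value=1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_property(self, n, seed):
        for train, test in make_splits(n, SplitScheme(n_models=3, master_seed=seed)):
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.union1d(train, test)) == n

    def test_too_few_animals(self):
        with pytest.raises(ValueError):
            make_splits(5, SplitScheme())


class TestPredictionError:
    def test_hand_fixtures(self):
        assert prediction_error([np.array([1.0, 2.0, 100.0])])["pe"] == 2.0
        two = prediction_error([np.array([10.0, 10.0]), np.array([20.0, 20.0])])
        assert two["pe"] == 15.0
        zero = prediction_error([np.zeros(5), np.zeros(3)])
        assert zero["pe"] == 0.0 and zero["iqr"] == 0.0

    def test_uniform_offset(self):
        # all predictions off by c -> PE = c
        c = 7.3
        stats = prediction_error([np.full(9, c), np.full(4, c)])
        assert stats["pe"] == pytest.approx(c)

    def test_quartile_consistency(self):
        rng = np.random.default_rng(0)
        stats = prediction_error([np.abs(rng.normal(size=30)) for _ in range(8)])
        assert stats["q1"] <= stats["pe"] <= stats["q3"]
        assert stats["iqr"] == pytest.approx(stats["q3"] - stats["q1"])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            prediction_error([])
        with pytest.raises(ValueError):
            prediction_error([np.array([])])


def _toy_problem(seed=0, n=60):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 4)) * 100
    y = 0.6 * X[:, 0] + 0.4 * X[:, 1] + rng.normal(0, 2, n)
    return pd.DataFrame(X, columns=[1, 2, 3, 4]), y


class TestRepeatedSplitForest:
    def test_perfect_predictor_near_zero_pe(self):
        y = np.linspace(0, 100, 60)
        ev = RepeatedSplitForest(scheme=SplitScheme(n_models=8, master_seed=1), n_estimators=60)
        rep = ev.evaluate(y[:, None], y)
        assert rep.pe < 2.0

    def test_pe_invariant_to_animal_order(self):
        X, y = _toy_problem()
        ev1 = RepeatedSplitForest(scheme=SplitScheme(n_models=6, master_seed=2), n_estimators=40)
        pe1 = ev1.evaluate(X.to_numpy(), y).pe
        perm = np.random.default_rng(0).permutation(len(y))
        # same split indices select different animals, but the PE statistic's
        # distribution is unchanged; with identical data multisets the value
        # is identical when the permutation is applied to both X and y rows
        pe2 = RepeatedSplitForest(
            scheme=SplitScheme(n_models=6, master_seed=2), n_estimators=40
        ).evaluate(X.to_numpy()[perm][np.argsort(perm)], y[perm][np.argsort(perm)]).pe
        assert pe1 == pe2

    def test_shared_splits_hash(self):
        X, y = _toy_problem()
        scheme = SplitScheme(n_models=4, master_seed=5)
        a = RepeatedSplitForest(scheme=scheme, n_estimators=20).evaluate(X.to_numpy(), y)
        b = RepeatedSplitForest(scheme=scheme, n_estimators=20).evaluate(y[:, None], y)
        assert a.split_hash == b.split_hash

    def test_compare_predictors(self):
        X, y = _toy_problem()
        scheme = SplitScheme(n_models=5, master_seed=7)
        good = RepeatedSplitForest(scheme=scheme, n_estimators=40).evaluate(
            X.to_numpy(), y, predictor="good", target="t"
        )
        same = RepeatedSplitForest(scheme=scheme, n_estimators=40).evaluate(
            X.to_numpy(), y, predictor="same", target="t"
        )
        table = compare_predictors([good, same])
        assert np.allclose(table["diff_vs_best"].abs(), table["diff_vs_best"].abs().iloc[0])
        assert table.loc[table.index[0], "diff_vs_best"] == 0.0

    def test_compare_rejects_different_splits(self):
        X, y = _toy_problem()
        a = RepeatedSplitForest(scheme=SplitScheme(n_models=4, master_seed=1),
                                n_estimators=20).evaluate(X.to_numpy(), y)
        b = RepeatedSplitForest(scheme=SplitScheme(n_models=4, master_seed=2),
                                n_estimators=20).evaluate(X.to_numpy(), y)
        with pytest.raises(ValueError, match="different splits"):
            compare_predictors([a, b])


class TestLocalMinimum:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ([5, 4, 3, 4, 2], (3, True)),
            ([5, 4, 3, 2, 1], (5, False)),       # monotone decreasing: last k, flagged
            ([3, 3, 3, 4, 5], (2, True)),        # plateau resolves to smallest interior k
            ([1, 2, 3], (3, False)),
        ],
    )
    def test_rule(self, curve, expected):
        assert first_local_minimum(curve) == expected


class TestImportanceAndInclusion:
    def test_informative_region_tops_ranking(self):
        X, y = _toy_problem(seed=3, n=90)
        ev = RepeatedSplitForest(scheme=SplitScheme(n_models=6, master_seed=0), n_estimators=60)
        ranking = oob_importance(X, y, ev)
        assert set(ranking.ranked_ids[:2]) == {1, 2}
        assert ranking.positive_regions[0] in (1, 2)
        # ties (if any) break by ascending region id
        s = ranking.scores
        assert list(s.index) == sorted(s.index, key=lambda r: (-s[r], r))

    def test_curve_matches_full_model_at_k_max(self):
        X, y = _toy_problem(seed=4, n=70)
        ev = RepeatedSplitForest(scheme=SplitScheme(n_models=5, master_seed=3),
                                 n_estimators=40, compute_oob=False)
        ranking = oob_importance(X, y, RepeatedSplitForest(
            scheme=SplitScheme(n_models=5, master_seed=3), n_estimators=40))
        curve = incremental_inclusion(ranking, X, y, ev, k_max=4)
        full = RepeatedSplitForest(scheme=SplitScheme(n_models=5, master_seed=3),
                                   n_estimators=40, compute_oob=False).evaluate(
            X[curve.regions_in_order].to_numpy(), y
        )
        assert curve.curve["pe"].iloc[-1] == pytest.approx(full.pe)

    def test_k_max_truncation_warns(self):
        X, y = _toy_problem(seed=5)
        ev = RepeatedSplitForest(scheme=SplitScheme(n_models=3, master_seed=1), n_estimators=20)
        ranking = oob_importance(X, y, ev)
        with pytest.warns(UserWarning, match="truncating"):
            curve = incremental_inclusion(ranking, X, y, ev, k_max=99)
        assert len(curve.curve) == X.shape[1]


class TestStratifiedPE:
    def _report(self):
        X, y = _toy_problem(seed=6)
        ev = RepeatedSplitForest(scheme=SplitScheme(n_models=6, master_seed=2), n_estimators=30)
        return ev.evaluate(X.to_numpy(), y)

    def test_single_grade_equals_overall(self):
        rep = self._report()
        strat = stratified_pe(rep, np.zeros(rep.n_animals, dtype=int))
        assert strat[0] == pytest.approx(rep.pe)

    def test_hand_computed_fixture(self):
        from strokecast.predict import PredictionReport, SplitScheme

        rep = PredictionReport(
            predictor="p", target="t", pe=0, q1=0, q3=0, iqr=0,
            per_model_medians=[], per_model_errors=[np.array([1.0, 5.0, 9.0])],
            per_model_test_indices=[np.array([0, 1, 2])], n_animals=4,
            scheme=SplitScheme(n_models=1), split_hash="h",
        )
        grades = np.array([0, 0, 3, 3])
        strat = stratified_pe(rep, grades)
        assert strat[0] == pytest.approx(3.0)   # median of {1, 5}
        assert strat[3] == pytest.approx(9.0)
        assert np.isnan(strat.get(1, np.nan))


class TestValidation:
    def test_identity_replication(self):
        X, y = _toy_problem(seed=8, n=60)
        ev = RepeatedSplitForest(scheme=SplitScheme(n_models=6, master_seed=4), n_estimators=40)
        base = ev.evaluate(X.to_numpy(), y)
        rep = validate_on_cohort(list(X.columns), X, y, ev, mode="refit")
        assert rep.pe == pytest.approx(base.pe)

    def test_missing_region_rejected(self):
        X, y = _toy_problem(seed=9)
        ev = RepeatedSplitForest(scheme=SplitScheme(n_models=3, master_seed=0), n_estimators=20)
        with pytest.raises(ValueError, match="missing kept regions"):
            validate_on_cohort([1, 99], X, y, ev)

    def test_transfer_mode(self):
        X, y = _toy_problem(seed=10, n=60)
        ev = RepeatedSplitForest(scheme=SplitScheme(n_models=4, master_seed=1), n_estimators=30)
        ev.fit(X.to_numpy(), y)
        rep = validate_on_cohort(list(X.columns), X, y, ev, mode="transfer", trained=ev)
        assert rep.pe < 6.0  # trained on the same animals: small errors


class TestSubcorticalLesions:
    def test_volume_suffices_without_cortical_involvement(self):
        """When lesions stay subcortical the region-resolved image adds no
        information over plain volume for the early deficit."""
        from strokecast import DeficitScorer, SimulationConfig, filter_regions, quantify_cohort, simulate_cohort

        diffs = []
        for seed in (1, 2):
            cfg = SimulationConfig(
                master_seed=seed, n_animals=100, n_sham=0,
                shell_penalty_mm=50.0, shell_penalty_jitter_sd=0.0,
            )
            cohort, _ = simulate_cohort(cfg)
            summary = DeficitScorer().score(cohort.behavior, "right").join(cohort.covariates)
            mcao = summary[summary.group == "mcao"]
            pct, vols = quantify_cohort([cohort.masks[a] for a in mcao.index], cohort.atlas)
            X = pct.loc[mcao.index, filter_regions(pct)]
            v = vols.loc[mcao.index, ["corrected_volume_mm3"]].to_numpy()
            y = mcao["subacute_pct_paretic"].to_numpy()
            scheme = SplitScheme(n_models=10, master_seed=seed)
            pe_vol = RepeatedSplitForest(scheme=scheme, n_estimators=60).evaluate(v, y).pe
            pe_seg = RepeatedSplitForest(scheme=scheme, n_estimators=60).evaluate(X.to_numpy(), y).pe
            diffs.append(pe_seg - pe_vol)
        assert np.mean(diffs) >= 0.0
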