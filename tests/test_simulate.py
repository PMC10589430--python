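"""Generator properties: atlas geometry, lesion topology, behavior model."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.stats import spearmanr

from strokecast import (
    SimulationConfig,
    build_toy_atlas,
    lesion_volume_in_atlas,
    region_lesion_percentages,
    simulate_behavior,
    simulate_cohort,
    simulate_lesion,
)
from strokecast.simulate import damage_score, deficit_link


class TestToyAtlas:
    def test_partition_and_hemispheres(self, small_atlas):
        counts = small_atlas.region_voxel_counts()
        assert len(counts) == 20
        assert (counts > 0).all()
        # region voxels partition the brain foreground exactly
        assert counts.sum() == small_atlas.foreground().sum()
        ont = small_atlas.ontology
        assert (ont["hemisphere"] == "L").sum() == 10
        assert (ont["hemisphere"] == "R").sum() == 10

    def test_mirror_symmetry(self, small_atlas):
        fg = small_atlas.foreground()
        assert np.array_equal(fg, np.flip(fg, axis=0))
        # labels mirror with a fixed id offset between hemispheres
        flipped = np.flip(small_atlas.labels, axis=0)
        left = small_atlas.hemisphere_mask("left") & fg
        assert np.array_equal(small_atlas.labels[left] + 10, flipped[left])

    def test_deterministic(self):
        a = build_toy_atlas(n_regions=20, atlas_shape=(32, 24, 24), seed=3)
        b = build_toy_atlas(n_regions=20, atlas_shape=(32, 24, 24), seed=3)
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"atlas_shape": (8, 8, 8)},
            {"n_regions": 19},
            {"n_regions": 10},
        ],
    )
    def test_bad_configuration_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_toy_atlas(**{"n_regions": 20, "atlas_shape": (32, 24, 24), **kwargs})


class TestLesionGrowth:
    def test_zero_severity_is_empty(self, small_atlas):
        mask = simulate_lesion(small_atlas, 45, 0.0, seed=1)
        assert mask.n_voxels == 0

    def test_connected_and_nested(self, small_atlas):
        ont = small_atlas.ontology
        core_ids = ont.index[(ont.structure_class == "core") & (ont.hemisphere == "L")]
        shell_ids = ont.index[ont.structure_class == "shell"]
        rng = np.random.default_rng(5)
        for i in range(25):
            mask = simulate_lesion(small_atlas, 45, float(rng.uniform(0.05, 1.0)), rng)
            if mask.n_voxels == 0:
                continue
            _, n_comp = ndimage.label(mask.mask)
            assert n_comp == 1
            # nesting: cortex-like damage implies striatum-like damage
            touches_shell = np.isin(small_atlas.labels[mask.mask], shell_ids).any()
            touches_core = np.isin(small_atlas.labels[mask.mask], core_ids).any()
            if touches_shell:
                assert touches_core

    def test_volume_grows_with_occlusion_time(self, small_atlas):
        vols = {}
        for occ in (30, 60):
            rng = np.random.default_rng(42)
            vols[occ] = np.mean(
                [
                    lesion_volume_in_atlas(
                        simulate_lesion(small_atlas, occ, float(rng.beta(3.5, 1.2)), rng),
                        small_atlas,
                    )
                    for _ in range(120)
                ]
            )
        assert vols[60] > vols[30]

    def test_deterministic(self, small_atlas):
        a = simulate_lesion(small_atlas, 45, 0.7, seed=9)
        b = simulate_lesion(small_atlas, 45, 0.7, seed=9)
        assert np.array_equal(a.mask, b.mask)

    def test_bad_severity_rejected(self, small_atlas):
        with pytest.raises(ValueError):
            simulate_lesion(small_atlas, 45, 1.5, seed=0)


class TestDeficitLink:
    def test_anchored_at_zero_and_saturating(self):
        assert deficit_link(0.0) == pytest.approx(0.0)
        assert deficit_link(1.0) == pytest.approx(0.97, abs=1e-9)
        u = np.linspace(0, 1, 50)
        d = deficit_link(u)
        assert (np.diff(d) > 0).all()

    def test_damage_score_zero_weights(self):
        pct = pd.Series([50.0, 80.0], index=[1, 2])
        assert damage_score(pct, pd.Series(dtype=float)) == 0.0


class TestBehaviorModel:
    def _config(self, **over):
        return SimulationConfig(**{"master_seed": 0, **over})

    def test_sham_stays_near_baseline(self):
        cfg = self._config()
        pct = pd.Series(0.0, index=range(1, 21))
        post = []
        for seed in range(30):
            rec, truth = simulate_behavior(pct, cfg, is_sham=True, seed=seed)
            base = rec[(rec.day >= -7) & (rec.side == "right") & (rec.day <= -1)]
            stroke = rec[(rec.day >= 12) & (rec.side == "right")]
            post.append(stroke.pellets_retrieved.mean() / base.pellets_retrieved.mean())
        assert np.mean(post) == pytest.approx(1.0, abs=0.05)

    def test_zero_weights_match_sham_in_expectation(self):
        cfg = self._config(deficit_weights=(0.0,) * 14)
        cohort, truth = simulate_cohort(
            SimulationConfig(
                master_seed=3, n_animals=25, n_sham=25, deficit_weights=(0.0,) * 14
            )
        )
        rec = cohort.behavior.merge(
            cohort.covariates[["group"]], left_on="animal_id", right_index=True
        )
        post = rec[(rec.day >= 2) & (rec.side == "right")]
        means = post.groupby("group")["pellets_retrieved"].mean()
        assert means["mcao"] == pytest.approx(means["sham"], rel=0.06)

    def test_fast_recovery_limit_equalizes_phases(self):
        # recovery_rate -> infinity: deficit sits at the residual level for
        # every post-stroke day, so subacute and residual phase means agree
        cfg = self._config(
            recovery_rate=60.0,
            acute_noise_sd=0.0,
            residual_noise_sd=0.0,
            non_recovery_max=0.0,
            daily_noise_sd=0.0,
            pellets_presented=4000,
        )
        pct = pd.Series(100.0, index=range(1, 15))
        weights = pd.Series(1.0, index=range(1, 15))
        rec, truth = simulate_behavior(
            pct, cfg, is_sham=False, seed=4, deficit_weights=weights
        )
        assert truth["true_subacute_pct"] == pytest.approx(truth["true_residual_pct"], abs=1e-6)
        daily = rec[rec.side == "right"].set_index("day")
        perf = daily.pellets_retrieved / daily.pellets_presented
        sub = perf.loc[2:6].mean()
        res = perf.loc[12:21].mean()
        assert sub == pytest.approx(res, abs=0.02)


class TestCohort:
    def test_size_and_determinism(self, tiny_cohort):
        cohort, truth = tiny_cohort
        assert len(cohort.animal_ids) == 12 + 3
        cohort2, truth2 = simulate_cohort(cohort.config)
        pd.testing.assert_frame_equal(cohort.behavior, cohort2.behavior)
        pd.testing.assert_frame_equal(truth.per_animal, truth2.per_animal)
        for a in cohort.animal_ids:
            assert np.array_equal(cohort.masks[a].mask, cohort2.masks[a].mask)

    def test_ground_truth_linkage(self):
        # weighted damage and the acute deficit are monotonically linked
        cfg = SimulationConfig(master_seed=8, n_animals=60, n_sham=0, acute_noise_sd=1e-6)
        cohort, truth = simulate_cohort(cfg)
        t = truth.per_animal
        rho = spearmanr(t.damage_score, t.acute_deficit).statistic
        assert rho > 0.8

    def test_null_covariates_carry_no_volume_signal(self):
        slopes = []
        for seed in range(4):
            cfg = SimulationConfig(
                master_seed=seed,
                n_animals=60,
                n_sham=0,
                surgeon_effect_mm3=0.0,
                genotype_effect_sd=0.0,
            )
            cohort, _ = simulate_cohort(cfg)
            from strokecast import quantify_cohort

            _, vols = quantify_cohort(
                [cohort.masks[a] for a in cohort.mcao_ids()], cohort.atlas
            )
            v = vols["lesion_volume_mm3"].to_numpy()
            surgeon = (cohort.covariates.loc[vols.index, "surgeon"] == "B").to_numpy()
            slopes.append(v[surgeon].mean() - v[~surgeon].mean())
        # surgeon difference fluctuates around zero across replicate cohorts
        assert abs(np.mean(slopes)) < 2.0

    def test_informative_regions_validated(self):
        with pytest.raises(ValueError, match="informative_region_ids"):
            simulate_cohort(
                SimulationConfig(master_seed=0, n_animals=6, n_sham=0,
                                 informative_region_ids=(999,), deficit_weights=(1.0,))
            )
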