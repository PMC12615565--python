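"""Seed extraction, GLM levels, TFCE and permutation inference."""

import numpy as np
import pandas as pd
import pytest

from respimeta import connectivity as cn
from respimeta import synthetic_data as sd

GEOM = sd.VolumeGeometry(
    shape=(10, 10, 6),
    seed_size=(2, 2, 2),
    seed_left_corner=(1, 1, 1),
    seed_right_corner=(7, 1, 1),
    target_corner=(4, 6, 2),
    target_size=(2, 2, 2),
)


def small_cohort_grids(n=12, effect=0.5, noise_sd=1.0, seed=0, n_t=60):
    cohort = sd.sample_cohort_traits(n, (n // 2, n - n // 2), seed=seed)
    grids = sd.simulate_volume_cohort(
        cohort,
        GEOM,
        sd.CouplingSpec(covariate="metacog_bias", baseline=0.4, effect=effect),
        noise_sd=noise_sd,
        n_timepoints=n_t,
        seed=seed + 1,
    )
    return cohort, grids


class TestExtractSeedSeries:
    def test_spatially_constant_volume(self):
        data = np.ones((4, 4, 2, 10)) * np.arange(10)
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        vol = sd.VolumeGrid(data, mask, ~mask & np.roll(mask, 1, 0), mask)
        np.testing.assert_allclose(
            cn.extract_seed_series(data, mask), np.arange(10, dtype=float)
        )

    def test_two_voxel_mean(self):
        data = np.zeros((2, 1, 1, 5))
        data[0, 0, 0] = np.arange(5)
        data[1, 0, 0] = np.arange(5) * 3
        mask = np.ones((2, 1, 1), dtype=bool)
        np.testing.assert_allclose(
            cn.extract_seed_series(data, mask), np.arange(5) * 2.0
        )

    def test_probabilistic_mask_thresholded_at_90(self):
        data = np.zeros((2, 1, 1, 4))
        data[0, 0, 0] = 1.0
        data[1, 0, 0] = 99.0
        prob = np.array([0.95, 0.85]).reshape(2, 1, 1)
        series = cn.extract_seed_series(data, prob)
        np.testing.assert_allclose(series, 1.0)  # only the 0.95 voxel survives

    def test_empty_after_threshold_rejected(self):
        data = np.zeros((2, 1, 1, 4))
        prob = np.full((2, 1, 1), 0.5)
        with pytest.raises(ValueError, match="0 of 2"):
            cn.extract_seed_series(data, prob)


class TestFirstLevelFc:
    def test_identity_regression(self):
        _, grids = small_cohort_grids(n=2, effect=0.0, noise_sd=0.0, n_t=40)
        g = grids[0]
        series = cn.extract_seed_series(g, g.seed_left)
        fl = cn.first_level_fc(g, series)
        np.testing.assert_allclose(fl.beta[g.seed_left], 1.0, atol=1e-10)
        np.testing.assert_allclose(fl.variance[g.seed_left], 0.0, atol=1e-12)

    def test_known_coefficient_recovery(self, rng):
        series = rng.standard_normal(120)
        data = np.empty((5, 4, 2, 120))
        data[:] = 0.5 * series + rng.normal(0, 0.1, size=(5, 4, 2, 120))
        mask = np.zeros((5, 4, 2), dtype=bool)
        mask[0, 0, 0] = True
        vol = sd.VolumeGrid(data, mask, np.roll(mask, 1, 0), mask)
        fl = cn.first_level_fc(vol, series)
        assert np.abs(fl.beta - 0.5).max() < 0.05

    def test_null_voxels_give_standard_normal_z(self, rng):
        series = rng.standard_normal(120)
        data = rng.standard_normal((10, 10, 10, 120))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[0, 0, 0] = True
        vol = sd.VolumeGrid(data, mask, np.roll(mask, 1, 0), mask)
        fl = cn.first_level_fc(vol, series)
        assert abs(fl.z.mean()) < 0.1
        assert abs(fl.z.std() - 1.0) < 0.1

    def test_constant_seed_rejected(self):
        _, grids = small_cohort_grids(n=2, n_t=20)
        with pytest.raises(ValueError, match="constant"):
            cn.first_level_fc(grids[0], np.ones(20))


class TestFixedEffects:
    @staticmethod
    def toy_map(beta, var):
        shape = (3, 3, 2)
        return cn.FirstLevelMap(
            np.full(shape, float(beta)), np.full(shape, float(var)), np.zeros(shape)
        )

    def test_identical_maps_zero_difference(self):
        fe = cn.fixed_effects_hemispheres(self.toy_map(2, 1), self.toy_map(2, 1))
        np.testing.assert_allclose(fe["left_minus_right"].beta, 0.0)
        np.testing.assert_allclose(fe["mean"].beta, 2.0)

    def test_equal_variance_mean_is_midpoint(self):
        fe = cn.fixed_effects_hemispheres(self.toy_map(2, 1), self.toy_map(1, 1))
        np.testing.assert_allclose(fe["mean"].beta, 1.5)

    def test_swapping_inputs_negates_difference(self):
        a, b = self.toy_map(2, 1), self.toy_map(0.5, 2)
        ab = cn.fixed_effects_hemispheres(a, b)["left_minus_right"].beta
        ba = cn.fixed_effects_hemispheres(b, a)["left_minus_right"].beta
        np.testing.assert_allclose(ab, -ba)

    def test_inverse_variance_weighting(self):
        # precise map (var 1) should dominate the noisy one (var 9): 0.9/0.1
        fe = cn.fixed_effects_hemispheres(self.toy_map(1, 1), self.toy_map(0, 9))
        np.testing.assert_allclose(fe["mean"].beta, 0.9)

    def test_shape_mismatch_rejected(self):
        small = cn.FirstLevelMap(np.zeros((2, 2, 2)), np.ones((2, 2, 2)), np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            cn.fixed_effects_hemispheres(self.toy_map(1, 1), small)


class TestBuildGroupDesign:
    @staticmethod
    def toy_cohort():
        return pd.DataFrame(
            {
                "id": ["a", "b", "c", "d"],
                "gender": ["M", "M", "F", "F"],
                "score": [1.0, 3.0, 2.0, 6.0],
                "gad7": [1, 2, 3, 4],
            }
        )

    def test_hand_demeaned_evs(self):
        d = cn.build_group_design(self.toy_cohort(), "score")
        np.testing.assert_allclose(d.X[:, 2], [-1, 1, 0, 0])
        np.testing.assert_allclose(d.X[:, 3], [0, 0, -2, 2])

    def test_measure_evs_sum_to_zero(self):
        cohort = sd.sample_cohort_traits(21, (10, 11), seed=5)
        d = cn.build_group_design(cohort, "metacog_bias")
        assert d.X[:, 2].sum() == pytest.approx(0.0, abs=1e-10)
        assert d.X[:, 3].sum() == pytest.approx(0.0, abs=1e-10)

    def test_gad7_covariates_extend_design(self):
        d = cn.build_group_design(self.toy_cohort(), "score", "measure_plus_gad7")
        assert d.X.shape[1] == 6
        assert d.ev_names[-2:] == ["gad7_male", "gad7_female"]

    def test_contrast_vectors_match_ev_count(self):
        d = cn.build_group_design(self.toy_cohort(), "score")
        for v in d.contrasts.values():
            assert v.shape == (d.X.shape[1],)
        np.testing.assert_allclose(
            d.contrasts["measure_positive"], -d.contrasts["measure_negative"]
        )

    def test_single_gender_drops_interaction_with_warning(self):
        cohort = self.toy_cohort().assign(gender="M")
        with pytest.warns(UserWarning, match="single-gender"):
            d = cn.build_group_design(cohort, "score")
        assert "gender_interaction" not in d.contrasts


class TestTfce:
    def test_all_zero_map(self):
        res = cn.tfce(np.zeros((4, 4, 4)))
        np.testing.assert_array_equal(res.enhanced, 0.0)

    def test_uniform_cluster_closed_form(self):
        """4-voxel cluster at height h0: enhancement -> e^0.5 * h0^3 / 3."""
        m = np.zeros((6, 6, 4))
        m[1:3, 1:3, 1] = 3.0
        res = cn.tfce(m, dh=3.0 / 400)
        np.testing.assert_allclose(res.enhanced[m > 0], 18.0, rtol=0.02)
        np.testing.assert_array_equal(res.enhanced[m == 0], 0.0)

    def test_height_scaling_cubes(self):
        m = np.zeros((6, 6, 4))
        m[1:3, 1:3, 1] = 3.0
        base = cn.tfce(m, dh=3.0 / 400).enhanced[m > 0]
        doubled = cn.tfce(2 * m, dh=6.0 / 400).enhanced[m > 0]
        np.testing.assert_allclose(doubled / base, 8.0, rtol=1e-6)

    def test_monotone_under_positive_shift(self, rng):
        m = np.abs(rng.standard_normal((8, 8, 4)))
        a = cn.tfce(m, dh=0.05).enhanced
        b = cn.tfce(m + 0.5, dh=0.05).enhanced
        assert np.all(b >= a - 1e-9)

    def test_negative_voxels_not_enhanced(self, rng):
        m = rng.standard_normal((8, 8, 4))
        res = cn.tfce(m, dh=0.05)
        assert np.all(res.enhanced[m <= 0] == 0.0)

    def test_non_finite_rejected(self):
        m = np.zeros((3, 3, 3))
        m[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            cn.tfce(m)

    def test_neighbourhood_changes_connectivity(self):
        # two diagonal voxels: one cluster under 26-connectivity, two under 6
        m = np.zeros((4, 4, 4))
        m[1, 1, 1] = m[2, 2, 2] = 2.0
        e26 = cn.tfce(m, dh=0.02, neighbourhood=26).enhanced[1, 1, 1]
        e6 = cn.tfce(m, dh=0.02, neighbourhood=6).enhanced[1, 1, 1]
        assert e26 > e6


class TestPermutationFwe:
    def test_minimum_attainable_p(self):
        cohort, grids = small_cohort_grids(n=14, effect=1.5, noise_sd=0.3)
        maps = _mean_maps(grids)
        design = cn.build_group_design(cohort, "metacog_bias")
        res = cn.permutation_fwe(maps, design, "measure_positive", n_perm=499, seed=0)
        assert res.fwe_p.min() >= 1.0 / 500
        assert res.n_permutations == 499

    def test_planted_effect_detected_in_target(self):
        cohort, grids = small_cohort_grids(n=20, effect=1.0, noise_sd=0.5, seed=3)
        maps = _mean_maps(grids)
        design = cn.build_group_design(cohort, "metacog_bias")
        res = cn.permutation_fwe(maps, design, "measure_positive", n_perm=300, seed=1)
        target = grids[0].target_mask
        assert (res.fwe_p[target] < 0.05).any()

    def test_noiseless_signal_localised_to_target(self):
        cohort, grids = small_cohort_grids(n=16, effect=0.8, noise_sd=0.0, seed=5)
        maps = _mean_maps(grids)
        design = cn.build_group_design(cohort, "metacog_bias")
        res = cn.permutation_fwe(maps, design, "measure_positive", n_perm=200, seed=2)
        sig = res.fwe_p < 0.05
        allowed = grids[0].target_mask | grids[0].seed_left | grids[0].seed_right
        assert sig.any()
        assert not np.any(sig & ~allowed)

    def test_exhaustive_enumeration_notice(self):
        rng = np.random.default_rng(0)
        cohort = pd.DataFrame(
            {
                "id": list("abcdef"),
                "gender": ["M", "F"] * 3,
                "score": rng.normal(size=6),
            }
        )
        maps = rng.standard_normal((6, 4, 4, 2))
        design = cn.build_group_design(cohort, "score")
        with pytest.warns(UserWarning, match="exhaustively"):
            res = cn.permutation_fwe(maps, design, "measure_positive",
                                     n_perm=1000, seed=0)
        assert res.n_permutations == 720

    def test_determinism(self):
        cohort, grids = small_cohort_grids(n=12, effect=0.5, seed=7)
        maps = _mean_maps(grids)
        design = cn.build_group_design(cohort, "metacog_bias")
        a = cn.permutation_fwe(maps, design, "measure_positive", n_perm=120, seed=9)
        b = cn.permutation_fwe(maps, design, "measure_positive", n_perm=120, seed=9)
        np.testing.assert_array_equal(a.fwe_p, b.fwe_p)

    def test_too_few_permutations_rejected(self):
        cohort, grids = small_cohort_grids(n=12, seed=8)
        design = cn.build_group_design(cohort, "metacog_bias")
        with pytest.raises(ValueError):
            cn.permutation_fwe(_mean_maps(grids), design, "measure_positive",
                               n_perm=10, seed=0)


def _mean_maps(grids):
    maps = []
    for g in grids:
        sl = cn.extract_seed_series(g, g.seed_left)
        sr = cn.extract_seed_series(g, g.seed_right)
        fe = cn.fixed_effects_hemispheres(
            cn.first_level_fc(g, sl), cn.first_level_fc(g, sr)
        )
        maps.append(fe["mean"].beta)
    return np.stack(maps)
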