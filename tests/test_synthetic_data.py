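"""Cohort copula, generative observers, synthetic volumes."""

import numpy as np
import pandas as pd
import pytest

from respimeta import synthetic_data as sd


class TestSampleCohortTraits:
    def test_row_count_and_gender_split_exact(self):
        t = sd.sample_cohort_traits(65, (32, 33), seed=0)
        assert len(t) == 65
        assert (t.gender == "F").sum() == 32
        assert (t.gender == "M").sum() == 33

    def test_bounds_respected(self):
        t = sd.sample_cohort_traits(500, (250, 250), seed=1)
        assert t.gad7.between(0, 21).all()
        assert t.metacog_bias.between(1, 10).all()
        assert (t.is_filters >= 1).all()
        assert (t.mratio_true > 0).all()

    def test_cohort_scale_means_match_printed_summaries(self):
        # n = 65 draw: GAD-7 and confidence means near their configured values
        t = sd.sample_cohort_traits(65, (32, 33), seed=2)
        assert abs(t.gad7.mean() - 2.85) < 0.9
        assert abs(t.metacog_bias.mean() - 6.22) < 0.5

    def test_marginal_fidelity_large_n(self):
        t = sd.sample_cohort_traits(2000, (1000, 1000), seed=3)
        spec = sd.DEFAULT_TRAIT_SPEC
        for name in ("gad7", "metacog_bias", "is_filters", "decision_c"):
            m = spec.marginals[name]
            se_mean = m.sd / np.sqrt(2000)
            # rounding adds variance 1/12 on integer-valued traits
            sd_expected = np.sqrt(m.sd**2 + (1 / 12 if m.integer else 0.0))
            assert abs(t[name].mean() - m.mean) < 3 * se_mean + 0.05
            assert abs(t[name].std() - sd_expected) < 3 * m.sd / np.sqrt(2 * 2000) + 0.05

    def test_identity_correlation_gives_independence(self):
        spec = sd.TraitSpec(
            sd.DEFAULT_TRAIT_SPEC.marginals, np.eye(len(sd.DEFAULT_TRAIT_SPEC.names))
        )
        t = sd.sample_cohort_traits(2000, (1000, 1000), trait_spec=spec, seed=4)
        numeric = t[spec.names]
        R = np.corrcoef(numeric.to_numpy(float).T)
        off = R[~np.eye(len(spec.names), dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_copula_recovers_planted_correlation(self):
        t = sd.sample_cohort_traits(2000, (1000, 1000), seed=5)
        r = np.corrcoef(t.gad7, t.metacog_bias)[0, 1]
        assert r == pytest.approx(-0.26, abs=0.06)

    def test_seed_determinism(self):
        a = sd.sample_cohort_traits(50, (25, 25), seed=6)
        b = sd.sample_cohort_traits(50, (25, 25), seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_non_psd_matrix_rejected(self):
        names = sd.DEFAULT_TRAIT_SPEC.names
        R = np.eye(len(names))
        R[0, 1] = R[1, 0] = 0.9
        R[0, 2] = R[2, 0] = 0.9
        R[1, 2] = R[2, 1] = -0.9  # jointly impossible
        with pytest.raises(ValueError, match="positive semi-definite"):
            sd.TraitSpec(sd.DEFAULT_TRAIT_SPEC.marginals, R)

    def test_bad_split_rejected(self):
        with pytest.raises(ValueError):
            sd.sample_cohort_traits(10, (4, 5), seed=0)

    def test_tsv_round_trip(self, tmp_path):
        t = sd.sample_cohort_traits(20, (10, 10), seed=7)
        sd.write_cohort(t, tmp_path / "cohort.tsv")
        back = sd.read_cohort(tmp_path / "cohort.tsv")
        pd.testing.assert_frame_equal(t, back)


class TestMakeObserver:
    def test_threshold_mapping_monotone(self):
        rows = [
            pd.Series(dict(is_filters=k, decision_c=0.0, mratio_true=0.8, metacog_bias=6.0))
            for k in (1, 8)
        ]
        slopes = [sd.make_observer(r).slope for r in rows]
        # fewer filters to threshold means a steeper psychometric slope
        assert slopes[0] > slopes[1]

    def test_ratio_rule(self, default_observer):
        for f in (1, 4, 7):
            assert default_observer.meta_d(f) == pytest.approx(
                default_observer.mratio_true * default_observer.d_prime(f)
            )

    def test_unity_mratio_equates_meta_d(self):
        row = pd.Series(dict(is_filters=3, decision_c=0.0, mratio_true=1.0, metacog_bias=6.0))
        obs = sd.make_observer(row)
        for f in (1, 3, 6):
            assert obs.meta_d(f) == pytest.approx(obs.d_prime(f))

    def test_accuracy_at_threshold_in_staircase_band(self, rng):
        row = pd.Series(dict(is_filters=4, decision_c=0.05, mratio_true=0.8, metacog_bias=6.0))
        obs = sd.make_observer(row)
        correct = 0
        for i in range(5000):
            cond = "resistance" if i % 2 == 0 else "sham"
            resp, _ = sd.observer_respond(obs, 4, cond, rng)
            correct += (cond == "resistance") == (resp == "yes")
        assert 0.65 <= correct / 5000 <= 0.85

    def test_mean_confidence_calibrated_to_trait(self, rng):
        for target in (3.5, 6.22, 8.5):
            row = pd.Series(
                dict(is_filters=4, decision_c=0.0, mratio_true=0.8, metacog_bias=target)
            )
            obs = sd.make_observer(row)
            confs = [
                sd.observer_respond(obs, 4, "resistance" if i % 2 == 0 else "sham", rng)[1]
                for i in range(4000)
            ]
            assert np.mean(confs) == pytest.approx(target, abs=0.25)


class TestObserverRespond:
    def test_null_sensitivity_equalises_rates(self, rng):
        obs = sd.ObserverParams(
            slope=0.0, threshold_filter=4, criterion_c=0.0, mratio_true=0.8
        )
        yes = {"resistance": 0, "sham": 0}
        for cond in yes:
            for _ in range(10_000):
                r, _ = sd.observer_respond(obs, 4, cond, rng)
                yes[cond] += r == "yes"
        assert abs(yes["resistance"] - yes["sham"]) / 10_000 < 0.03

    def test_conservative_criterion_suppresses_yes(self, rng):
        obs = sd.ObserverParams(
            slope=0.25, threshold_filter=4, criterion_c=1.0, mratio_true=0.8,
            lapse_rate=0.0,
        )
        yes = 0
        for i in range(10_000):
            cond = "resistance" if i % 2 == 0 else "sham"
            r, _ = sd.observer_respond(obs, 4, cond, rng)  # d' = 1 at level 4
            yes += r == "yes"
        assert yes / 10_000 < 0.5

    def test_zero_mratio_decouples_confidence_from_accuracy(self, rng):
        obs = sd.ObserverParams(
            slope=0.337, threshold_filter=4, criterion_c=0.0, mratio_true=0.0,
            lapse_rate=0.0,
        )
        conf, acc = [], []
        for i in range(10_000):
            cond = "resistance" if i % 2 == 0 else "sham"
            r, k = sd.observer_respond(obs, 4, cond, rng)
            conf.append(k)
            acc.append((cond == "resistance") == (r == "yes"))
        r_pb = np.corrcoef(conf, np.asarray(acc, dtype=float))[0, 1]
        assert abs(r_pb) < 0.03

    def test_psychometric_monotone_in_filters(self, default_observer, rng):
        accs = []
        for level in (1, 3, 5, 7):
            correct = sum(
                (cond == "resistance")
                == (sd.observer_respond(default_observer, level, cond, rng)[0] == "yes")
                for i in range(5000)
                for cond in ["resistance" if i % 2 == 0 else "sham"]
            )
            accs.append(correct / 5000)
        assert all(b >= a - 0.02 for a, b in zip(accs, accs[1:]))


class TestSimulateVolumeCohort:
    @pytest.fixture
    def small_geometry(self):
        return sd.VolumeGeometry(
            shape=(10, 10, 6),
            seed_size=(2, 2, 2),
            seed_left_corner=(1, 1, 1),
            seed_right_corner=(7, 1, 1),
            target_corner=(4, 6, 2),
            target_size=(2, 2, 2),
        )

    def test_noiseless_identity(self, small_geometry):
        cohort = sd.sample_cohort_traits(3, (2, 1), seed=8)
        grids = sd.simulate_volume_cohort(
            cohort,
            small_geometry,
            sd.CouplingSpec(baseline=1.0, effect=0.0),
            noise_sd=0.0,
            n_timepoints=40,
            seed=9,
        )
        for g in grids:
            seed_series = g.data[g.seed_left].mean(axis=0)
            for voxel in g.data[g.target_mask]:
                np.testing.assert_allclose(voxel, seed_series, atol=1e-12)

    def test_masks_disjoint_and_nonempty(self, small_geometry):
        cohort = sd.sample_cohort_traits(2, (1, 1), seed=10)
        g = sd.simulate_volume_cohort(
            cohort, small_geometry, n_timepoints=20, seed=0
        )[0]
        assert not np.any(g.seed_left & g.seed_right)
        assert g.seed_left.sum() == g.seed_right.sum() == 8

    def test_null_effect_leaves_coupling_unrelated_to_covariate(self, small_geometry):
        from respimeta import connectivity as cn

        cohort = sd.sample_cohort_traits(40, (20, 20), seed=11)
        grids = sd.simulate_volume_cohort(
            cohort,
            small_geometry,
            sd.CouplingSpec(covariate="metacog_bias", baseline=0.4, effect=0.0),
            noise_sd=1.0,
            n_timepoints=60,
            seed=12,
        )
        couplings = []
        for g in grids:
            series = cn.extract_seed_series(g, g.seed_left)
            fl = cn.first_level_fc(g, series)
            couplings.append(fl.beta[g.target_mask].mean())
        r = np.corrcoef(cohort.metacog_bias, couplings)[0, 1]
        assert abs(r) < 0.15

    def test_short_series_rejected(self, small_geometry):
        cohort = sd.sample_cohort_traits(2, (1, 1), seed=0)
        with pytest.raises(ValueError):
            sd.simulate_volume_cohort(cohort, small_geometry, n_timepoints=5, seed=0)

    def test_unknown_covariate_rejected(self, small_geometry):
        cohort = sd.sample_cohort_traits(2, (1, 1), seed=0)
        with pytest.raises(KeyError):
            sd.simulate_volume_cohort(
                cohort,
                small_geometry,
                sd.CouplingSpec(covariate="nope"),
                n_timepoints=20,
                seed=0,
            )

    def test_nifti_round_trip(self, small_geometry, tmp_path):
        cohort = sd.sample_cohort_traits(2, (1, 1), seed=13)
        g = sd.simulate_volume_cohort(
            cohort, small_geometry, n_timepoints=20, seed=14
        )[0]
        sd.save_volume(g, tmp_path / "sub01")
        back = sd.load_volume(tmp_path / "sub01")
        np.testing.assert_allclose(back.data, g.data, atol=1e-6)
        np.testing.assert_array_equal(back.seed_left, g.seed_left)
        np.testing.assert_array_equal(back.target_mask, g.target_mask)

    def test_seed_determinism(self, small_geometry):
        cohort = sd.sample_cohort_traits(3, (2, 1), seed=15)
        a = sd.simulate_volume_cohort(cohort, small_geometry, n_timepoints=20, seed=16)
        b = sd.simulate_volume_cohort(cohort, small_geometry, n_timepoints=20, seed=16)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.data, gb.data)
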