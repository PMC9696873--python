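import numpy as np
import pandas as pd
import pytest
from scipy import stats

import retestkit as rk
from retestkit.aggregation import AggregationRule, matrix_from_dataset
from retestkit.datamodel import ConfigError, Variable
from retestkit.reliability import icc_mean, icc_single, mean_squares
from retestkit.synthetic import (
    GeneratorConfig,
    HopGeneratorConfig,
    generate_hops,
    generate_trials,
    reference_fixture,
    simulate_icc_recovery,
    true_values,
)


def _cfg(**kw):
    base = dict(variable=Variable.GRIP_FORCE, mu=46.0, sigma_subject=12.0,
                sigma_interaction=0.9, sigma_trial=1.4, seed=123)
    base.update(kw)
    return GeneratorConfig(**base)


class TestDeterminism:
    def test_same_seed_gives_identical_datasets(self):
        a, _ = generate_trials(_cfg())
        b, _ = generate_trials(_cfg())
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_different_seed_differs(self):
        a, _ = generate_trials(_cfg(seed=1))
        b, _ = generate_trials(_cfg(seed=2))
        assert not a.trials["value"].equals(b.trials["value"])

    def test_variable_substreams_are_independent(self):
        # the same variable drawn alone or alongside others is unchanged
        alone, _ = generate_trials(_cfg(seed=77, variable=Variable.PEAK_TORQUE,
                                        mu=256, sigma_subject=90,
                                        sigma_interaction=8, sigma_trial=12))
        other, _ = generate_trials(_cfg(seed=77))  # different variable, same seed
        again, _ = generate_trials(_cfg(seed=77, variable=Variable.PEAK_TORQUE,
                                        mu=256, sigma_subject=90,
                                        sigma_interaction=8, sigma_trial=12))
        pd.testing.assert_frame_equal(alone.trials, again.trials)
        assert not np.allclose(alone.trials["value"].to_numpy()[:10],
                               other.trials["value"].to_numpy()[:10])


class TestTruth:
    def test_noise_free_data_give_icc_exactly_one(self):
        ds, _ = generate_trials(_cfg(sigma_interaction=0.0, sigma_trial=0.0))
        Y = matrix_from_dataset(ds, Variable.GRIP_FORCE, AggregationRule.AVG)
        ms = mean_squares(Y)
        assert icc_single(ms).estimate == pytest.approx(1.0, abs=1e-12)
        assert icc_mean(ms).estimate == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_truth(self):
        # sigma_b=30, sigma_s=8, sigma_e=10, T=3: 900 / (900 + 64 + 100/3)
        cfg = _cfg(mu=100, sigma_subject=30, sigma_interaction=8, sigma_trial=10)
        truth = true_values(cfg)
        expected = 900 / (900 + 64 + 100 / 3)
        assert truth.true_icc_single == pytest.approx(expected, rel=1e-12)
        assert truth.true_icc_single == pytest.approx(0.9024, abs=5e-4)
        k = 3
        assert truth.true_icc_mean == pytest.approx(
            k * expected / (1 + (k - 1) * expected), rel=1e-12)

    def test_session_effect_enters_truth_denominator(self):
        quiet = true_values(_cfg())
        shifted = true_values(_cfg(session_effects=(0.0, 0.0, 6.0)))
        assert shifted.true_icc_single < quiet.true_icc_single
        assert shifted.expected_session_means == (46.0, 46.0, 52.0)

    def test_moments_at_large_n(self):
        cfg = _cfg(n_subjects=2000, mu=100.0, sigma_subject=10.0,
                   sigma_interaction=1.0, sigma_trial=2.0,
                   session_effects=(0.0, 5.0, 10.0), seed=99)
        ds, _ = generate_trials(cfg)
        Y = matrix_from_dataset(ds, Variable.GRIP_FORCE, AggregationRule.AVG)
        emp_subject_sd = Y.values.mean(axis=1).std(ddof=1)
        assert emp_subject_sd == pytest.approx(10.0, rel=0.02)
        shifts = Y.values.mean(axis=0) - Y.values.mean(axis=0)[0]
        assert shifts[1] == pytest.approx(5.0, rel=0.02)
        assert shifts[2] == pytest.approx(10.0, rel=0.02)

    def test_recovery_truth_matches_generator_truth(self):
        rec = simulate_icc_recovery(0.8, 1.0, replicates=5, seed=1)
        cfg = _cfg(sigma_subject=1.0, sigma_interaction=0.8, sigma_trial=1.0, mu=10)
        assert rec.true_icc == pytest.approx(true_values(cfg).true_icc_single)


class TestConfigValidation:
    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigError):
            _cfg(sigma_trial=-1.0)

    def test_session_effects_length_checked(self):
        with pytest.raises(ConfigError):
            _cfg(session_effects=(0.0, 1.0))

    def test_invalid_prob_above_half_rejected(self):
        with pytest.raises(ConfigError):
            HopGeneratorConfig(invalid_prob=0.9)


class TestHops:
    def test_zero_invalid_prob_gives_full_sets(self):
        ds = generate_hops(HopGeneratorConfig(invalid_prob=0.0, seed=5))
        counts = ds.hops.groupby(["subject_id", "session_id", "set_index"])["valid"].sum()
        assert (counts == 10).all()

    def test_default_invalid_rate_near_five_percent(self):
        ds = generate_hops(HopGeneratorConfig(seed=8))
        counts = ds.hops.groupby(["subject_id", "session_id", "set_index"])["valid"].sum()
        # binomial mean 10 * 0.95 = 9.5 over 17*3*2 = 102 sets
        assert counts.mean() == pytest.approx(9.5, abs=0.2)

    def test_every_set_has_a_valid_hop(self):
        ds = generate_hops(HopGeneratorConfig(invalid_prob=0.5, seed=13))
        counts = ds.hops.groupby(["subject_id", "session_id", "set_index"])["valid"].sum()
        assert (counts >= 1).all()

    def test_hop_values_positive(self):
        ds = generate_hops(HopGeneratorConfig(seed=21))
        assert (ds.hops["contact_time"] > 0).all()
        assert (ds.hops["peak_force"] > 0).all()


class TestLognormalOption:
    def test_right_skewed_and_positive(self):
        cfg = _cfg(n_subjects=2000, mu=2.0, sigma_subject=2.0,
                   sigma_interaction=0.0, sigma_trial=0.5,
                   distribution="lognormal", seed=31)
        ds, _ = generate_trials(cfg)
        vals = ds.trials["value"].to_numpy()
        assert (vals > 0).all()
        assert stats.skew(vals) > 0.5


class TestReferenceFixture:
    def test_fixed_seed_reproducible(self, fixture_dataset):
        dataset, _ = fixture_dataset
        again, _ = reference_fixture()
        pd.testing.assert_frame_equal(dataset.trials, again.trials)
        pd.testing.assert_frame_equal(dataset.hops, again.hops)

    def test_covers_all_tests_at_study_size(self, fixture_dataset):
        dataset, _ = fixture_dataset
        assert len(dataset.subjects) == 17
        assert dataset.session_order == ["S1", "S2", "S3"]
        per_var = dataset.trials.groupby("variable").size()
        assert (per_var == 17 * 3 * 3).all()  # 3 trials x 3 sessions
        assert len(dataset.hops) == 17 * 3 * 2 * 10

    def test_knee_extension_scale_matches_study(self, fixture_dataset):
        dataset, _ = fixture_dataset
        Y = matrix_from_dataset(dataset, Variable.PEAK_TORQUE, AggregationRule.AVG)
        assert Y.values[:, 0].mean() == pytest.approx(256.2, abs=10)

    def test_mvc_reliability_excellent_and_act_not(self, fixture_report):
        frame = fixture_report.reliability_frame()
        mvc = frame[frame.variable.isin(["peak_torque", "grip_force"])]
        assert (mvc.icc > 0.90).all()
        act_all = frame.query(
            "variable == 'hop_contact_time' and rule == 'avg' and comparison == 'all'"
        )
        assert float(act_all.icc.iloc[0]) < 0.75

    def test_session_cvs_in_printed_band(self, fixture_report):
        frame = fixture_report.reliability_frame()
        assert frame.cv_pct.between(0.5, 8.5).all()
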