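"""Shift statistic, sign-test classification, bootstrap and normality tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from approachscan import (
    AnalysisConfig,
    DensityCurve,
    NeuronModel,
    ShiftResult,
    bootstrap_max_significance,
    classify_shift,
    joint_chance_level,
    normality_and_clusters,
    pairwise_shift_distribution,
    shift_statistic,
    sign_test_exact,
    simulate_recording,
    spike_density,
)


class TestShiftStatistic:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [(2000.0, 1000.0, 100.0), (1500.0, 1500.0, 0.0), (1500.0, 1000.0, 50.0)],
    )
    def test_examples(self, m1, m2, expected):
        assert shift_statistic(m1, m2) == pytest.approx(expected)

    def test_invalid_m2(self):
        with pytest.raises(ValueError):
            shift_statistic(1000.0, 0.0)
        with pytest.raises(ValueError):
            shift_statistic(1000.0, -5.0)

    @given(
        m1=st.floats(100.0, 3000.0),
        m2=st.floats(100.0, 3000.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, m1, m2, scale):
        """The shift is a ratio: rescaling all distances leaves it unchanged."""
        assert shift_statistic(m1 * scale, m2 * scale) == pytest.approx(
            shift_statistic(m1, m2), rel=1e-9
        )


class TestPairwiseShifts:
    def test_six_trials_give_36_pairs(self):
        pw = pairwise_shift_distribution(np.arange(1, 7) * 300.0, np.arange(1, 7) * 150.0)
        assert len(pw) == 36

    def test_constant_lists_give_zero(self):
        pw = pairwise_shift_distribution([800.0] * 4, [800.0] * 5)
        assert len(pw) == 20
        np.testing.assert_allclose(pw, 0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        m1 = rng.uniform(500, 2500, 6)
        m2 = rng.uniform(300, 1500, 6)
        pw = pairwise_shift_distribution(m1, m2)
        oracle = sorted(
            (a - b) / b * 100.0 for a in m1 for b in m2
        )
        np.testing.assert_allclose(sorted(pw), oracle)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pairwise_shift_distribution([], [100.0])
        with pytest.raises(ValueError):
            pairwise_shift_distribution([100.0], [0.0])


class TestSignTest:
    @pytest.mark.parametrize("n,k", [(5, 5), (10, 8), (20, 15), (36, 26), (36, 36)])
    def test_matches_closed_form_binomial(self, n, k):
        """Exact sign test equals the closed-form binomial tail (ties dropped)."""
        x = np.concatenate([np.ones(k), -np.ones(n - k)])
        p = sign_test_exact(x, 0.0, "greater")
        closed = sum(math.comb(n, j) for j in range(k, n + 1)) / 2**n
        assert p == pytest.approx(closed, rel=1e-12)
        p_less = sign_test_exact(x, 0.0, "less")
        closed_less = sum(math.comb(n, j) for j in range(0, k + 1)) / 2**n
        assert p_less == pytest.approx(closed_less, rel=1e-12)

    def test_ties_dropped(self):
        x = np.array([1.0, 1.0, 0.0, 0.0, -1.0])
        # 3 non-ties, 2 positive
        assert sign_test_exact(x, 0.0, "greater") == pytest.approx(
            (math.comb(3, 2) + math.comb(3, 3)) / 8
        )

    def test_all_ties_returns_one(self):
        assert sign_test_exact(np.zeros(5), 0.0, "greater") == 1.0


class TestClassifyShift:
    def _result(self, shifts):
        shifts = np.asarray(shifts, dtype=float)
        sr = ShiftResult(
            m1_mm=2000.0,
            m2_mm=1000.0,
            shift_pct=100.0,
            pairwise_shifts_pct=shifts,
            n_pairs=len(shifts),
            mean_pairwise_shift_pct=float(shifts.mean()),
        )
        return sr

    def test_all_high_shifts_labelled_shifting(self):
        rng = np.random.default_rng(0)
        sr = self._result(rng.uniform(90, 110, 36))
        assert classify_shift(sr) == "shifting"
        # all 36 signs positive: p = 2^-36
        assert sr.p_sign == pytest.approx(2.0**-36, rel=1e-9)

    def test_all_low_shifts_labelled_constant(self):
        rng = np.random.default_rng(1)
        sr = self._result(rng.uniform(-10, 10, 36))
        assert classify_shift(sr) == "constant"
        assert sr.p_sign == pytest.approx(2.0**-36, rel=1e-9)

    def test_intermediate_shifts_unclassified(self):
        rng = np.random.default_rng(2)
        sr = self._result(rng.uniform(45, 55, 36))
        assert classify_shift(sr) == "unclassified"

    def test_mean_above_threshold_but_sign_test_fails(self):
        # mean > 70 but half the pairs below the boundary: not significant
        shifts = np.concatenate([np.full(18, 270.0), np.full(18, 60.0)])
        sr = self._result(shifts)
        assert classify_shift(sr) == "unclassified"

    def test_too_few_pairs_warns(self):
        sr = self._result([95.0, 105.0, 99.0, 101.0])
        with pytest.warns(UserWarning, match="pairs"):
            assert classify_shift(sr) == "unclassified"

    def test_scale_invariance_of_classification(self):
        m1 = np.array([1900.0, 2000.0, 2100.0, 1950.0, 2050.0, 2000.0])
        m2 = m1 / 2.0
        for scale in (1.0, 0.37, 12.0):
            sr = ShiftResult.from_trial_maxima(m1 * scale, m2 * scale, 2000.0 * scale, 1000.0 * scale)
            assert classify_shift(sr) == "shifting"


def test_joint_chance_level():
    assert joint_chance_level(0.05) == pytest.approx(0.0025)


class TestBootstrapMaxSignificance:
    def test_identical_flat_trials_not_significant(self, short_trajectory, fast_cfg):
        from approachscan.synth import Trial
        from approachscan import GratingSpec

        spikes = np.arange(0.05, short_trajectory.end_time_s, 0.2)
        trial = Trial(GratingSpec(38.0), short_trajectory, spikes)
        curves = [spike_density(trial, fast_cfg) for _ in range(6)]
        est = bootstrap_max_significance(curves, fast_cfg, seed=0)
        assert not est.significant

    def test_requires_two_trials(self, short_trajectory, fast_cfg):
        from approachscan.synth import Trial
        from approachscan import GratingSpec

        trial = Trial(GratingSpec(38.0), short_trajectory, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            bootstrap_max_significance([spike_density(trial, fast_cfg)], fast_cfg)

    def test_strong_peak_detected_across_seeds(self, short_protocol, fast_cfg):
        """distance-tuned response at peak/baseline = 5 is significant in
        (essentially) every seeded run (Monte-Carlo oracle)."""
        m = NeuronModel(
            archetype="distance_tuned",
            optimal_distance_mm=550.0,
            distance_sigma_mm=150.0,
            baseline_rate_hz=4.0,
            peak_rate_hz=20.0,
        )
        hits = 0
        n_runs = 50
        for s in range(n_runs):
            rec = simulate_recording(m, short_protocol, n_trials_per_grating=6, seed=s)
            curves = [spike_density(t, fast_cfg) for t in rec.trials_for("1F")]
            est = bootstrap_max_significance(curves, fast_cfg, seed=10_000 + s)
            hits += est.significant
        assert hits >= n_runs - 1

    def test_deterministic_given_seed(self, short_protocol, fast_cfg):
        m = NeuronModel(archetype="distance_tuned", optimal_distance_mm=500.0)
        rec = simulate_recording(m, short_protocol, seed=2)
        curves = [spike_density(t, fast_cfg) for t in rec.trials_for("1F")]
        a = bootstrap_max_significance(curves, fast_cfg, seed=5)
        b = bootstrap_max_significance(curves, fast_cfg, seed=5)
        assert a.threshold_hz == b.threshold_hz and a.significant == b.significant


class TestNormalityAndClusters:
    def test_normal_sample_rarely_rejected(self):
        """Calibration: a genuinely normal shift sample (n = 24, the constant
        cluster scale) passes the per-cluster Lilliefors test >= 90% of draws."""
        rng = np.random.default_rng(0)
        passes = 0
        n_draws = 500
        for _ in range(n_draws):
            x = rng.normal(0.0, 13.0, 24)
            s = normality_and_clusters(x)
            # all values fall below the 50% split -> constant cluster
            p = s.constant_cluster["lilliefors_p"]
            passes += p > 0.05
        assert passes / n_draws >= 0.90

    def test_two_cluster_mixture_rejected_pooled(self):
        """A mixture of the two empirical clusters (6.5 +/- 13.3 and
        113 +/- 30.3) fails pooled normality at alpha = 0.001 in >= 95% of draws."""
        rng = np.random.default_rng(1)
        rejects = 0
        n_draws = 200
        for _ in range(n_draws):
            x = np.concatenate(
                [rng.normal(6.5, 13.3, 25), rng.normal(113.0, 30.3, 24)]
            )
            s = normality_and_clusters(x)
            rejects += s.pooled_lilliefors[1] <= 0.001
            # and the split clusters individually look normal
        assert rejects / n_draws >= 0.95

    def test_cluster_means_and_sds(self):
        rng = np.random.default_rng(2)
        lo = rng.normal(5.0, 10.0, 30)
        hi = rng.normal(100.0, 20.0, 30)
        s = normality_and_clusters(np.concatenate([lo, hi]))
        assert s.constant_cluster["mean_pct"] == pytest.approx(lo.mean())
        assert s.shifting_cluster["mean_pct"] == pytest.approx(hi.mean())
        assert s.constant_cluster["sd_pct"] == pytest.approx(lo.std(ddof=1))

    def test_single_point_skipped(self):
        s = normality_and_clusters([42.0])
        assert s.pooled_lilliefors is None
        assert s.notes

    def test_position_clusters_found(self):
        rng = np.random.default_rng(3)
        pos = np.concatenate([rng.normal(800, 60, 25), rng.normal(2200, 80, 25)])
        shifts = rng.normal(5, 10, 50)
        s = normality_and_clusters(shifts, constant_positions_mm=pos)
        assert s.position_clusters["n_components"] == 2
        means = s.position_clusters["means_mm"]
        assert means[0] == pytest.approx(800, abs=50)
        assert means[1] == pytest.approx(2200, abs=50)
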