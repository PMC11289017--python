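import numpy as np
import pandas as pd
import pytest

from conftest import make_stream
from gazebench import (
    axis_correlations,
    classify_eccentricity,
    cohort_correlations,
    data_loss_fraction,
    drift_correct,
    fixation_accuracy,
    merge_streams,
    precision_across_subjects,
    rms_s2s,
)
from gazebench.quality import AxisCorrelation


class TestFixationAccuracy:
    def test_zero_at_target(self):
        assert fixation_accuracy((1.0, 2.0), (1.0, 2.0)) == 0.0

    def test_3_4_5(self):
        assert fixation_accuracy((0.3, 0.4), (0.0, 0.0)) == pytest.approx(0.5)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fixation_accuracy((np.nan, 0.0), (0.0, 0.0))


class TestEccentricity:
    def test_corner_outer(self):
        assert classify_eccentricity(0, 0, 7, 8) == "outer"

    def test_interior_inner(self):
        assert classify_eccentricity(3, 4, 7, 8) == "inner"

    def test_ring_count_7x8(self):
        # counting oracle: ring size = 2r + 2c - 4
        labels = [classify_eccentricity(r, c, 7, 8)
                  for r in range(7) for c in range(8)]
        assert labels.count("outer") == 2 * 7 + 2 * 8 - 4 == 26
        assert labels.count("inner") == 30

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_eccentricity(7, 0, 7, 8)


class TestPrecisionAcrossSubjects:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["subject", "tracker", "location",
                                           "cx_deg", "cy_deg"])

    def test_identical_centroids_zero_sd(self):
        t = self._table([(f"s{i}", "web", "L0", 1.0, 2.0) for i in range(5)])
        per_loc, _ = precision_across_subjects(t)
        assert per_loc["sd_x_deg"].iloc[0] == 0.0
        assert per_loc["sd_y_deg"].iloc[0] == 0.0

    def test_two_point_sd(self):
        t = self._table([("s1", "web", "L0", -1.0, 0.0),
                         ("s2", "web", "L0", 1.0, 0.0)])
        per_loc, _ = precision_across_subjects(t)
        assert per_loc["sd_x_deg"].iloc[0] == pytest.approx(np.sqrt(2))

    def test_single_subject_location_excluded(self):
        t = self._table([("s1", "web", "L0", 0.0, 0.0),
                         ("s1", "web", "L1", 0.0, 0.0),
                         ("s2", "web", "L1", 1.0, 1.0)])
        per_loc, summary = precision_across_subjects(t)
        assert not per_loc.set_index("location").loc["L0", "included"]
        assert summary["n_locations"].iloc[0] == 1

    def test_variance_composition_recovered(self):
        # between-subject bias SD beta plus centroid noise sigma:
        # pooled SD -> sqrt(beta^2 + sigma^2) within 15% over 50 locations
        rng = np.random.default_rng(21)
        beta, sigma = 0.6, 0.2
        n_subj, n_loc = 12, 50
        bias = rng.normal(0, beta, (n_subj, 2))
        rows = []
        for s in range(n_subj):
            for loc in range(n_loc):
                c = bias[s] + rng.normal(0, sigma, 2)
                rows.append((f"s{s}", "web", f"L{loc}", c[0], c[1]))
        per_loc, summary = precision_across_subjects(self._table(rows))
        # the between-subject component is the SD of the 12 drawn biases
        # (its own sampling error at n=12 is ~20%), composed with sigma
        exp_x = np.hypot(bias[:, 0].std(ddof=1), sigma)
        exp_y = np.hypot(bias[:, 1].std(ddof=1), sigma)
        assert summary["mean_sd_x_deg"].iloc[0] == pytest.approx(
            exp_x, rel=0.15)
        assert summary["mean_sd_y_deg"].iloc[0] == pytest.approx(
            exp_y, rel=0.15)


class TestRmsS2S:
    def test_constant_zero(self):
        assert rms_s2s(np.full(10, 3.0)) == 0.0

    def test_alternating_unit_steps(self):
        assert rms_s2s(np.array([0.0, 1.0, 0.0, 1.0])) == 1.0

    def test_white_noise_sqrt2(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.7, 20_000)
        assert rms_s2s(x) == pytest.approx(0.7 * np.sqrt(2), rel=0.03)

    def test_pairs_spanning_invalid_excluded(self):
        x = np.array([0.0, 0.0, 100.0, 0.0, 0.0])
        valid = np.array([True, True, False, True, True])
        assert rms_s2s(x, valid) == 0.0

    def test_needs_consecutive_pair(self):
        with pytest.raises(ValueError):
            rms_s2s(np.array([1.0, 2.0]), np.array([True, False]))


class TestDataLoss:
    def test_confidence_share(self):
        conf = np.array([1.0] * 8 + [0.0] * 2)
        t = np.arange(10) * 33.0
        x = np.where(conf > 0, 700.0, np.nan)
        st = make_stream(t, x, x, confidence=conf, validity=conf > 0)
        assert data_loss_fraction(st) == pytest.approx(20.0)

    def test_complete_stream_no_loss(self):
        t = np.arange(300) / 30.0 * 1000.0
        st = make_stream(t, np.full(300, 1.0), np.full(300, 1.0),
                         rate_hz=30.0)
        assert data_loss_fraction(st, mode="missing") == 0.0

    def test_missing_mode_binomial(self):
        # dropout 5% over 10^4 samples: within ~3 binomial SEs
        rng = np.random.default_rng(8)
        keep = rng.random(10_000) >= 0.05
        t = (np.arange(10_000) * 2.0)[keep]
        st = make_stream(t, np.full(keep.sum(), 1.0),
                         np.full(keep.sum(), 1.0), rate_hz=500.0)
        loss = data_loss_fraction(st, interval_ms=(0.0, 19_998.0),
                                  mode="missing")
        assert loss == pytest.approx(5.0, abs=0.7)

    def test_bounds(self):
        t = np.arange(10) * 10.0
        st = make_stream(t, np.ones(10), np.ones(10), rate_hz=50.0)
        loss = data_loss_fraction(st, mode="missing")
        assert 0.0 <= loss <= 100.0


class TestAxisCorrelations:
    def test_affine_copy_perfect(self, geom):
        rng = np.random.default_rng(12)
        t = np.arange(0, 40_000, 33.0)
        x = 700 + np.cumsum(rng.normal(0, 2, t.size))
        y = 450 + np.cumsum(rng.normal(0, 2, t.size))
        a = make_stream(t, x, y, source="a")
        merged = merge_streams(a, make_stream(t.copy(), x.copy(), y.copy(),
                                              source="b"), geom,
                               known_lag_ms=0.0)
        ac = axis_correlations(merged)
        assert ac.r_x == pytest.approx(1.0, abs=1e-9)
        assert ac.r_y == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_zero(self, geom):
        rng = np.random.default_rng(13)
        t = np.arange(10_000) * 33.0
        a = make_stream(t, 700 + rng.normal(0, 30, t.size),
                        450 + rng.normal(0, 30, t.size), source="a")
        b = make_stream(t.copy(), 700 + rng.normal(0, 30, t.size),
                        450 + rng.normal(0, 30, t.size), source="b")
        merged = merge_streams(a, b, geom, known_lag_ms=0.0)
        ac = axis_correlations(merged)
        assert abs(ac.r_x) < 0.05
        assert abs(ac.r_y) < 0.05

    def test_min_valid_exclusion(self, geom):
        t = np.arange(10) * 33.0
        a = make_stream(t, np.ones(10), np.ones(10), source="a")
        merged = merge_streams(a, make_stream(t.copy(), np.ones(10),
                                              np.ones(10), source="b"),
                               geom, known_lag_ms=0.0)
        with pytest.raises(ValueError, match="excluded"):
            axis_correlations(merged, min_valid=30)

    def test_cohort_mean_plain_and_fisher(self):
        per_subject = [AxisCorrelation(0.8, 0.6, 100),
                       AxisCorrelation(0.4, 0.2, 100)]
        rx, ry = cohort_correlations(per_subject)
        assert rx == pytest.approx(0.6)
        assert ry == pytest.approx(0.4)
        fx, fy = cohort_correlations(per_subject, fisher=True)
        assert fx == pytest.approx(np.tanh(np.mean(np.arctanh([0.8, 0.4]))))
        assert fy == pytest.approx(np.tanh(np.mean(np.arctanh([0.6, 0.2]))))


class TestDriftCorrect:
    TARGETS = np.array([[0.0, 0.0], [3.0, 0.0], [-3.0, 0.0],
                        [0.0, 2.0], [0.0, -2.0], [2.0, 2.0], [-2.0, -2.0]])

    def test_zero_offsets_identity(self):
        samples = np.array([[1.0, 1.0], [2.0, 2.0]])
        corrected, corr, resid = drift_correct(samples, self.TARGETS,
                                               self.TARGETS)
        np.testing.assert_allclose(corrected, samples)
        np.testing.assert_allclose(corr, [0.0, 0.0])
        assert resid == 0.0

    def test_constant_bias_recovered(self):
        bias = np.array([1.0, -0.5])
        samples = np.array([[0.0, 0.0], [5.0, 5.0]]) + bias
        corrected, corr, resid = drift_correct(samples,
                                               self.TARGETS + bias,
                                               self.TARGETS)
        np.testing.assert_allclose(corr, bias)
        np.testing.assert_allclose(corrected,
                                   [[0.0, 0.0], [5.0, 5.0]], atol=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_noisy_bias_improves_accuracy(self):
        rng = np.random.default_rng(17)
        bias = np.array([1.0, -0.5])
        sigma = 0.2
        improved = 0
        for _ in range(20):
            cents = self.TARGETS + bias + rng.normal(0, sigma,
                                                     self.TARGETS.shape)
            gaze = np.array([[0.0, 0.0]]) + bias
            corrected, corr, resid = drift_correct(cents[:, :], cents,
                                                   self.TARGETS)
            # residual is on the noise scale, not the bias scale
            assert resid < np.linalg.norm(bias)
            assert resid == pytest.approx(sigma * np.sqrt(np.pi / 2),
                                          rel=1.5)
            before = np.linalg.norm(gaze - 0.0)
            after = np.linalg.norm(gaze - corr)
            if after <= before:
                improved += 1
        assert improved >= 18

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            drift_correct(np.zeros((1, 2)), np.zeros((2, 2)),
                          np.zeros((2, 2)))
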