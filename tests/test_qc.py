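"""QIBA-style QC metric tests: formulas, thresholds, Pearson, SNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dwiqc import (QCThresholds, RepeatSeries, adc_bias_estimate,
                   adc_noise_estimate, b_value_dependence, cv_repeatability,
                   pearson, pearson_ci, qc_report, repeatability_coefficient,
                   snr_ndyn)
from dwiqc.exceptions import UndefinedSNRError, ValidationError
from dwiqc.roi import ROIStats

#: Printed spatial-variation profiles: distance (cm) -> relative error (%).
HORIZONTAL = ((0, 2, 4, 6, 8, 10, 12, 14, 16, 18),
              (0.0, 1.6, -6.3, -5.5, -2.3, -3.9, -1.6, 3.1, -1.6, 0.8))
VERTICAL = ((0, 2, 4, 6, 8), (0.0, -0.9, 9.3, 13.0, 24.1))


def repeats(*means):
    return RepeatSeries(tuple(ROIStats(n=10, mean=m, sd=0.0) for m in means))


class TestRepeatability:
    def test_identical_means_zero_cv(self):
        assert cv_repeatability(repeats(1e-3, 1e-3, 1e-3)) == 0.0

    def test_cv_hand_formula(self):
        rep = repeats(1.0e-3, 1.1e-3)
        hand = 100 * np.std([1.0e-3, 1.1e-3], ddof=1) / np.mean([1.0e-3, 1.1e-3])
        assert cv_repeatability(rep) == pytest.approx(hand, rel=1e-12)
        assert cv_repeatability(rep) == pytest.approx(6.734, abs=5e-4)

    def test_cv_scale_invariant(self):
        rep1 = repeats(2.0e-3, 2.1e-3, 1.9e-3)
        rep2 = repeats(6.0e-3, 6.3e-3, 5.7e-3)  # everything scaled by 3
        assert cv_repeatability(rep1) == pytest.approx(cv_repeatability(rep2),
                                                       rel=1e-12)

    def test_rc_is_277_sigma(self):
        means = (2.0e-3, 2.1e-3, 1.9e-3, 2.0e-3)
        rep = repeats(*means)
        assert repeatability_coefficient(rep) == pytest.approx(
            2.77 * np.std(means, ddof=1), rel=1e-12)
        assert repeatability_coefficient(repeats(1e-3, 1e-3)) == 0.0

    def test_cv_needs_two_repeats_and_positive_mean(self):
        with pytest.raises(ValidationError):
            cv_repeatability(repeats(1e-3))


class TestBiasNoiseBdep:
    def test_bias_at_truth_is_zero(self):
        assert adc_bias_estimate(1.1e-3, 1.1e-3) == (0.0, 0.0)

    @pytest.mark.parametrize("mu, expected_pct", [
        (1.2e-3, 100 * (1.2 - 1.1) / 1.1),   # +9.0909 %
        (1.0e-3, 100 * (1.0 - 1.1) / 1.1),   # -9.0909 %
    ])
    def test_bias_sign_and_magnitude(self, mu, expected_pct):
        absolute, pct = adc_bias_estimate(mu, 1.1e-3)
        assert pct == pytest.approx(expected_pct, rel=1e-12)
        assert absolute == pytest.approx(mu - 1.1e-3, rel=1e-12)

    def test_noise_estimate(self):
        assert adc_noise_estimate(ROIStats(n=50, mean=1.0e-3, sd=0.09e-3)) \
            == pytest.approx(9.0, rel=1e-12)
        assert adc_noise_estimate(ROIStats(n=50, mean=1e-3, sd=0.0)) == 0.0

    def test_b_dependence_asymmetric(self):
        assert b_value_dependence(1.000e-3, 1.007e-3) == pytest.approx(
            0.7, rel=1e-9)
        assert b_value_dependence(1.007e-3, 1.000e-3) == pytest.approx(
            0.6951, abs=5e-5)
        assert b_value_dependence(1e-3, 1e-3) == 0.0


class TestSNR:
    def test_identical_repeats_undefined(self):
        vols = [np.full((8, 8, 2), 50.0)] * 4
        with pytest.raises(UndefinedSNRError):
            snr_ndyn(vols, np.ones((8, 8, 2), bool))

    def test_gaussian_noise_expectation(self):
        """Constant 100 + N(0, 2) noise over 4 repeats: SNR approximates
        100 / (2 * c4(4)) within 5 % (c4 corrects the sample-SD bias)."""
        rng = np.random.default_rng(42)
        vols = [100.0 + rng.normal(0, 2.0, (60, 60, 1)) for _ in range(4)]
        got = snr_ndyn(vols, np.ones((60, 60, 1), bool))
        c4 = np.sqrt(2 / 3) * 1.0 / (np.sqrt(np.pi) / 2)  # Gamma(2)/Gamma(1.5)
        expected = 100.0 / (2.0 * c4)
        assert got == pytest.approx(expected, rel=0.05)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        vols = [100.0 + rng.normal(0, 3.0, (20, 20, 1)) for _ in range(4)]
        roi = np.ones((20, 20, 1), bool)
        assert snr_ndyn([2 * v for v in vols], roi) == pytest.approx(
            snr_ndyn(vols, roi), rel=1e-12)


class TestPearson:
    def test_perfect_linear(self):
        x = [0.0, 1.0, 2.0, 3.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_vertical_profile_r_095(self):
        assert round(pearson(*VERTICAL), 2) == 0.95

    def test_horizontal_profile_r_025(self):
        assert round(pearson(*HORIZONTAL), 2) == 0.25

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    # magnitudes bounded away from the subnormal range, where the product of
    # the two sums of squares would underflow in any formulation
    _coord = st.floats(-50, 50).filter(lambda v: v == 0 or abs(v) > 1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(_coord, _coord), min_size=3, max_size=30))
    def test_matches_bruteforce_and_scipy(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        try:
            r = pearson(x, y)
        except ValidationError:
            return  # degenerate draw
        # brute-force covariance / SD oracle
        xm = sum(x) / len(x)
        ym = sum(y) / len(y)
        cov = sum((a - xm) * (b - ym) for a, b in zip(x, y))
        vx = sum((a - xm) ** 2 for a in x)
        vy = sum((b - ym) ** 2 for b in y)
        assert r == pytest.approx(cov / (vx * vy) ** 0.5, abs=1e-12)
        assert r == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-9)

    def test_ci_brackets_r(self):
        lo, hi = pearson_ci(0.95, 5)
        assert lo < 0.95 < hi and -1 < lo and hi < 1


class TestReport:
    def test_perfect_phantom_all_pass(self, icewater_noiseless):
        """Noiseless unbiased ice-water run: zero bias and CV, every claim met,
        SNR flagged undefined rather than failed."""
        rep = icewater_noiseless.report
        for p in rep.pairs:
            assert p.cv_r == 0.0
            assert abs(p.bias_pct) < 1e-9
            assert all(p.passes.values())
        assert rep.b_dependence_pct == pytest.approx(0.0, abs=1e-9)
        assert rep.snr is None and rep.snr_pass is None
        assert rep.all_pass

    def test_global_scale_injection_fails_only_bias(self):
        """A +4 % ADC scale trips the 3.6 % bias claim and nothing else."""
        mu = 1.1e-3 * 1.04
        rep = {(0.0, 800.0): RepeatSeries(tuple(
            ROIStats(n=100, mean=mu, sd=mu * 0.001) for _ in range(4)))}
        report = qc_report(rep)
        (metrics,) = report.pairs
        assert not metrics.passes["bias"]
        assert metrics.passes["cv_r"] and metrics.passes["rc_r"] \
            and metrics.passes["noise"]
        assert not report.all_pass

    def test_boundary_equality_fails(self):
        """Claims use strict '<': a metric exactly at its limit does not pass."""
        rep = RepeatSeries(tuple(ROIStats(n=10, mean=m, sd=0.0)
                                 for m in (1.0e-3, 1.02e-3)))
        cv = cv_repeatability(rep)
        thr = QCThresholds(cv_max=cv)  # threshold placed exactly at the metric
        report = qc_report({(0.0, 800.0): rep}, thresholds=thr)
        assert not report.pairs[0].passes["cv_r"]

    def test_thresholds_config_round_trip(self, tmp_path):
        import yaml
        from dwiqc.io import read_thresholds_yaml
        path = tmp_path / "thr.yaml"
        path.write_text(yaml.safe_dump({"cv_max": 1.5, "rc_max": 1.5e-5,
                                        "bias_max": 3.6, "noise_max": 2.0,
                                        "bdep_max": 2.0, "snr_min": 50.0}))
        thr = read_thresholds_yaml(path)
        assert thr == QCThresholds()
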