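"""Profile likelihood: threshold, walker, intervals, PLB_crit, screens."""

import math

import numpy as np
import pytest
from scipy import stats

import plsched as P
from plsched.model import scenario
from plsched.profiles import (DEFAULT_THRESHOLD, ConfidenceInterval,
                              ThresholdSpec, confidence_interval,
                              walk_profile)


class TestThreshold:
    def test_default_value(self):
        spec = ThresholdSpec()
        # independent check: the CDF inverts back to alpha
        assert stats.chi2.cdf(spec.delta_chi2, 1) == pytest.approx(0.68,
                                                                   abs=1e-12)
        assert round(spec.delta_chi2, 2) == 0.99

    def test_validation(self):
        with pytest.raises(ValueError):
            ThresholdSpec(alpha=1.2)
        with pytest.raises(ValueError):
            ThresholdSpec(dof=0)


class TestPlbCritArithmetic:
    def test_single_parameter_band(self):
        ci = ConfidenceInterval(lower=0.5, upper=1.5)
        assert P.plb_crit([ci], np.array([1.0])) == pytest.approx(0.5)

    def test_two_parameters_add_in_quadrature(self):
        cis = [ConfidenceInterval(0.5, 1.5), ConfidenceInterval(1.0, 3.0)]
        assert P.plb_crit(cis, np.array([1.0, 2.0])) == pytest.approx(
            math.sqrt(0.5))

    def test_nonfinite_bound_is_inf(self):
        cis = [ConfidenceInterval(0.5, math.inf, upper_finite=False)]
        assert P.plb_crit(cis, np.array([1.0])) == math.inf

    def test_zero_theta_hat_rejected(self):
        with pytest.raises(ValueError):
            P.plb_crit([ConfidenceInterval(0.0, 1.0)], np.array([0.0]))


class TestWalker:
    def test_quadratic_profile_closed_form(self):
        # psi = a (theta - 2)^2 crosses the threshold at 2 +- sqrt(d/a)
        a = 7.3
        curve = walk_profile(lambda th: a * (th - 2.0) ** 2, 2.0, 0.0)
        ci = confidence_interval(curve)
        half = math.sqrt(DEFAULT_THRESHOLD.delta_chi2 / a)
        assert ci.finite
        assert ci.lower == pytest.approx(2.0 - half, rel=1e-4)
        assert ci.upper == pytest.approx(2.0 + half, rel=1e-4)

    def test_linear_model_matches_standard_error(self):
        """For y = theta*x with known sigma the PL interval equals
        theta_hat +- sqrt(delta_chi2) * SE with SE = sigma/sqrt(sum x^2)."""
        rng = np.random.default_rng(42)
        x = rng.uniform(0.5, 2.0, 25)
        sigma = 0.3
        theta_true = 1.4
        y = theta_true * x + rng.normal(0, sigma, x.size)
        theta_hat = float(np.dot(x, y) / np.dot(x, x))

        def psi(th):
            return float(np.sum(((th * x - y) / sigma) ** 2))

        curve = walk_profile(psi, theta_hat, psi(theta_hat))
        ci = confidence_interval(curve, psi(theta_hat))
        se = sigma / math.sqrt(np.dot(x, x))
        half = math.sqrt(DEFAULT_THRESHOLD.delta_chi2) * se
        assert ci.lower == pytest.approx(theta_hat - half, rel=1e-4)
        assert ci.upper == pytest.approx(theta_hat + half, rel=1e-4)

    def test_flat_profile_is_unidentifiable(self):
        curve = walk_profile(lambda th: 0.0, 1.0, 0.0)
        ci = confidence_interval(curve)
        assert not ci.lower_finite and not ci.upper_finite
        assert ci.lower == -math.inf and ci.upper == math.inf


class TestPKProfiles:
    def test_profile_minimum_at_truth_and_monotone(self):
        scen = scenario(1, 1)
        times = P.uniform_schedule(8)
        clean = P.observe(P.simulate(scen), times)
        sig = np.full(8, P.default_sigma(scen))
        data = P.Dataset(times, clean, sig)
        res = P.fit(data, scen, scen.free_theta)
        curve = P.profile_parameter(0, data, scen, res)
        assert np.all(curve.psi_profile >= -1e-10)
        ih = int(np.argmin(np.abs(curve.grid - curve.theta_hat)))
        assert curve.psi_profile[ih] == pytest.approx(0.0, abs=1e-10)
        # non-decreasing away from the optimum on noise-free data
        assert np.all(np.diff(curve.psi_profile[ih:]) > -1e-8)
        assert np.all(np.diff(curve.psi_profile[:ih + 1]) < 1e-8)

    def test_generic_and_kernel_paths_agree(self):
        scen = scenario(1, 1)
        times = P.uniform_schedule(8)
        clean = P.observe(P.simulate(scen), times)
        sig = np.full(8, P.default_sigma(scen))
        data = P.Dataset(times, clean, sig)
        res = P.fit(data, scen, scen.free_theta)
        report = P.identifiability_screen(scen, times)
        for i in range(2):
            curve = P.profile_parameter(i, data, scen, res)
            ci = confidence_interval(curve)
            fast = report.intervals[i]
            assert ci.lower == pytest.approx(fast.lower, rel=2e-3)
            assert ci.upper == pytest.approx(fast.upper, rel=2e-3)

    def test_adding_a_sample_never_hurts(self):
        scen = scenario(1, 1)
        base = np.array([0.0, 40.0, 80.0, 150.0, 300.0, 500.0])
        extra = np.sort(np.append(base, 220.0))
        m_base = P.plb_crit_noise_free(scen, base)
        m_extra = P.plb_crit_noise_free(scen, extra)
        assert m_extra <= m_base * (1 + 1e-6)

    def test_interval_width_scales_with_sigma(self):
        scen = scenario(1, 1)
        times = P.uniform_schedule(10)
        s = P.default_sigma(scen)
        wide = P.identifiability_screen(scen, times, sigma=s)
        narrow = P.identifiability_screen(scen, times, sigma=s / 2)
        for ci_w, ci_n in zip(wide.intervals, narrow.intervals):
            ratio = ci_w.width / ci_n.width
            assert ratio == pytest.approx(2.0, rel=0.05)

    def test_metric_matches_screen_intervals(self):
        scen = scenario(2, 1)
        times = P.uniform_schedule(10)
        report = P.identifiability_screen(scen, times)
        assert P.plb_crit_noise_free(scen, times) == pytest.approx(
            report.metric, rel=1e-6)


class TestScreen:
    def test_case1_uniform_passes(self):
        report = P.identifiability_screen(scenario(1, 1), P.uniform_schedule(10))
        assert report.passed
        assert all(ci.finite for ci in report.intervals)

    def test_screen_report_serialises(self, tmp_path):
        report = P.identifiability_screen(scenario(1, 1), P.uniform_schedule(10))
        doc = report.to_json(tmp_path / "screen.json")
        assert doc["passed"] is True
        assert set(doc["parameters"]) == {"k", "u_n"}
        assert (tmp_path / "screen.json").exists()
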