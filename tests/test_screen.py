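"""Screen metrics: growth-rate fitting, phage AUC, blood viability, table."""

import numpy as np
import pytest

from capkit.screen import (blood_viability, fit_growth_rate,
                           phage_sensitivity_auc, screen_summary)
from capkit.synthetic import (CfuSeries, DEFAULT_LOD, GrowthCurve,
                              GrowthParams, generate_growth_curve)


def _curve(mu, cv=0.0, seed=0, od0=0.05, k=1.0):
    p = GrowthParams(od0=od0, mu_max=mu, carrying_capacity=k, noise_cv=cv)
    return generate_growth_curve(p, np.linspace(0, 12, 49), seed=seed)


class TestGrowthRateFit:
    def test_noiseless_recovery_within_1pct(self):
        fit = fit_growth_rate(_curve(0.8))
        assert fit.converged
        assert abs(fit.mu_max - 0.8) / 0.8 < 0.01

    def test_flat_curve_returns_zero(self):
        c = GrowthCurve(times=np.linspace(0, 6, 10),
                        od600=np.full(10, 0.05))
        fit = fit_growth_rate(c)
        assert fit.mu_max == 0.0
        assert "no net growth" in fit.note

    def test_noisy_replicates_median_error_below_10pct(self):
        errs = []
        for s in range(30):
            fit = fit_growth_rate(_curve(1.0, cv=0.05, seed=s))
            errs.append(abs(fit.mu_max - 1.0))
        assert np.median(errs) <= 0.10

    def test_scale_equivariance(self):
        c = _curve(0.7)
        scaled = GrowthCurve(times=c.times, od600=c.od600 * 3.0)
        f1, f2 = fit_growth_rate(c), fit_growth_rate(scaled)
        assert abs(f1.mu_max - f2.mu_max) < 1e-3 * f1.mu_max + 1e-9

    def test_too_few_points_raise(self):
        c = GrowthCurve(times=np.array([0.0, 1, 2, 3.0]),
                        od600=np.array([0.05, 0.1, 0.2, 0.4]))
        with pytest.raises(ValueError):
            fit_growth_rate(c)

    def test_loglinear_alternative_close_on_clean_data(self):
        fit = fit_growth_rate(_curve(1.2), method="loglinear")
        assert abs(fit.mu_max - 1.2) / 1.2 < 0.15


class TestPhageAuc:
    @pytest.mark.parametrize("od_fn,expected,tol", [
        (lambda t: np.full_like(t, 0.5), 3.0, 1e-12),   # rectangle
        (lambda t: t / 6.0, 3.0, 1e-12),                # linear ramp, exact
        (lambda t: t ** 2, 72.0, 1e-3),                 # quadratic
    ])
    def test_against_analytic_integrals(self, od_fn, expected, tol):
        t = np.arange(0, 6.0001, 0.01)
        c = GrowthCurve(times=t, od600=od_fn(t))
        assert phage_sensitivity_auc(c, 6.0) == pytest.approx(expected,
                                                              abs=tol)

    def test_additive_over_adjacent_windows(self):
        t = np.arange(0, 6.0001, 0.05)
        c = GrowthCurve(times=t, od600=np.exp(0.3 * t))
        full = phage_sensitivity_auc(c, 6.0)
        first = phage_sensitivity_auc(c, 3.0)
        shifted = GrowthCurve(times=t[t >= 3.0] - 3.0, od600=c.od600[t >= 3.0])
        second = phage_sensitivity_auc(shifted, 3.0)
        assert full == pytest.approx(first + second, rel=1e-9)

    def test_window_past_last_sample_raises(self):
        c = GrowthCurve(times=np.linspace(0, 4, 10),
                        od600=np.full(10, 0.3))
        with pytest.raises(ValueError):
            phage_sensitivity_auc(c, 6.0)


class TestBloodViability:
    def _series(self, censored_at_6=False):
        v = np.array([1e6, 1e5, 3e4])
        c = np.array([False, False, censored_at_6])
        if censored_at_6:
            v[2] = DEFAULT_LOD
        return CfuSeries(times=np.array([0.0, 2.0, 6.0]), cfu_per_ml=v,
                         lod=DEFAULT_LOD, censored=c)

    def test_lookup(self):
        assert blood_viability(self._series()) == (3e4, False)

    def test_censored_at_lod(self):
        assert blood_viability(self._series(True)) == (DEFAULT_LOD, True)

    def test_out_of_range_raises(self):
        s = CfuSeries(times=np.array([0.0, 4.0]),
                      cfu_per_ml=np.array([1e6, 1e4]), lod=DEFAULT_LOD,
                      censored=np.array([False, False]))
        with pytest.raises(ValueError):
            blood_viability(s, at_h=6.0)


class TestScreenSummary:
    def _fit(self, mu):
        from capkit.screen import GrowthFit
        return GrowthFit(mu_max=mu, carrying_capacity=1.0, od0=0.05,
                         rss=0.0, converged=True)

    def test_single_strain_degenerate_scores_one(self):
        df = screen_summary([self._fit(1.0)], [(1e5, False)], [3.0], ["EcN"])
        assert df[["growth_score", "viability_score",
                   "phage_score"]].iloc[0].tolist() == [1.0, 1.0, 1.0]

    def test_minmax_and_censoring_rule(self):
        df = screen_summary([self._fit(1.0), self._fit(0.5)],
                            [(1e5, False), (DEFAULT_LOD, True)],
                            [6.0, 2.0], ["a", "b"])
        assert df["phage_score"].tolist() == [1.0, 0.0]
        assert df["viability_score"].tolist() == [1.0, 0.0]
        assert df["growth_score"].tolist() == [1.0, 0.0]

    def test_mismatched_strain_sets_raise(self):
        with pytest.raises(ValueError):
            screen_summary([self._fit(1.0)], [], [3.0], ["a"])
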