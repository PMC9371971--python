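"""Generators: closed-form noiseless limits, determinism, Monte-Carlo means."""

import numpy as np
import pytest

from capkit.synthetic import (DEFAULT_LOD, GrowthParams, TEMGeometry,
                              generate_biodistribution, generate_blood_killing,
                              generate_growth_curve, generate_tem_image,
                              generate_tox_cohort, logistic_od,
                              toxicity_probability)


class TestGrowthCurve:
    def test_zero_growth_is_constant(self):
        p = GrowthParams(od0=0.07, mu_max=0.0, carrying_capacity=1.0)
        c = generate_growth_curve(p, np.linspace(0, 10, 20), seed=0)
        assert np.allclose(c.od600, 0.07)

    def test_noiseless_matches_logistic_closed_form(self):
        t = np.linspace(0, 12, 40)
        p = GrowthParams(od0=0.05, mu_max=1.0, carrying_capacity=1.0)
        c = generate_growth_curve(p, t, seed=0)
        expected = 1.0 * 0.05 * np.exp(t) / (1.0 - 0.05 + 0.05 * np.exp(t))
        assert np.max(np.abs(c.od600 - expected)) < 1e-12

    def test_same_seed_bit_identical(self):
        t = np.linspace(0, 8, 30)
        p = GrowthParams(od0=0.05, mu_max=0.9, carrying_capacity=1.2,
                         noise_cv=0.05)
        a = generate_growth_curve(p, t, seed=42)
        b = generate_growth_curve(p, t, seed=42)
        assert np.array_equal(a.od600, b.od600)

    def test_lysis_decays_exponentially_after_onset(self):
        t = np.linspace(0, 8, 33)
        p = GrowthParams(od0=0.05, mu_max=1.0, carrying_capacity=1.0,
                         lysis_delay=3.5, lysis_rate=2.0)
        c = generate_growth_curve(p, t, seed=0)
        od_onset = logistic_od(np.array([3.5]), 0.05, 1.0, 1.0)[0]
        post = t >= 3.5
        assert np.allclose(c.od600[post],
                           od_onset * np.exp(-2.0 * (t[post] - 3.5)))
        assert c.od600[-1] < 0.01 * od_onset

    def test_invalid_inputs_raise(self):
        p = GrowthParams(od0=0.05, mu_max=1.0, carrying_capacity=1.0)
        with pytest.raises(ValueError):
            generate_growth_curve(p, np.array([0.0, 1.0, 1.0]), seed=0)
        with pytest.raises(ValueError):
            GrowthParams(od0=1.5, mu_max=1.0, carrying_capacity=1.0)


class TestBloodKilling:
    def test_no_killing_identity(self):
        s = generate_blood_killing(1e5, 0.0, DEFAULT_LOD,
                                   np.array([0.0, 1.0, 6.0]), seed=0,
                                   noise=False)
        assert np.allclose(s.cfu_per_ml, 1e5)
        assert not s.censored.any()

    def test_expected_below_lod_is_censored(self):
        # n0 * exp(-10) ~ 4.5 CFU/ml, far under the 2e2 CFU/ml floor
        s = generate_blood_killing(1e5, 20.0, DEFAULT_LOD,
                                   np.array([0.5]), seed=3)
        assert s.censored[0]
        assert s.cfu_per_ml[0] == DEFAULT_LOD

    def test_plating_mean_matches_analytic_expectation(self):
        n0, k, t = 1e5, 20.0, 0.1
        true_conc = n0 * np.exp(-k * t)
        vals = np.array([
            generate_blood_killing(n0, k, DEFAULT_LOD, np.array([t]),
                                   seed=s).cfu_per_ml[0]
            for s in range(1000)])
        # plating at dilution 10^m targeting 30-300 colonies: the per-sample
        # variance is Poisson in colony counts scaled back to CFU/ml
        import math
        m = math.ceil(math.log10(true_conc * 0.1 / 300.0))
        lam = true_conc * 0.1 / 10 ** m
        se = math.sqrt(lam / 1000) * 10 ** m / 0.1
        assert abs(vals.mean() - true_conc) < 3 * se

    def test_empty_times_raise(self):
        with pytest.raises(ValueError):
            generate_blood_killing(1e5, 1.0, DEFAULT_LOD, np.array([]), seed=0)


class TestToxCohort:
    def test_midpoint_and_step_limit(self):
        assert toxicity_probability(4.4e7, 4.4e7, 4.0) == 0.5
        assert toxicity_probability(2 * 4.4e7, 4.4e7, 200.0) > 1 - 1e-12

    def test_empirical_fractions_within_3se(self):
        doses = np.array([1e6, 1e7, 4.4e7, 2e8])
        cohort = generate_tox_cohort(doses, 4.4e7, 4.0, 500, seed=11)
        p = toxicity_probability(doses, 4.4e7, 4.0)
        se = np.sqrt(p * (1 - p) / 500)
        assert np.all(np.abs(cohort.fractions - p) <= 3 * se + 1e-12)

    def test_frame_round_trip(self):
        from capkit.synthetic import ToxCohort
        cohort = generate_tox_cohort([1e6, 1e7], 5e6, 2.0, 5, seed=0)
        back = ToxCohort.from_frame(cohort.to_frame())
        assert np.array_equal(back.doses, cohort.doses)
        assert all(np.array_equal(a, b)
                   for a, b in zip(back.outcomes, cohort.outcomes))


class TestTEMImage:
    def test_degenerate_distribution_gives_constant_truth(self):
        img = generate_tem_image([(60.0, 0.0, 1.0)], TEMGeometry(), 0.0,
                                 seed=0)
        assert np.allclose(img.truth["thickness_nm"], 60.0)

    def test_ring_pixel_count_matches_annulus_area(self):
        geo = TEMGeometry(cell_radius_nm=600.0, nm_per_px=4.0, wobble=0.0)
        img = generate_tem_image([(80.0, 0.0, 1.0)], geo, 0.0, seed=0)
        r_in, r_out = 600.0, 680.0
        expected = np.pi * (r_out ** 2 - r_in ** 2) / 4.0 ** 2
        count = img.truth["ring_mask"].sum()
        assert abs(count - expected) / expected < 0.05

    def test_bimodal_spec_gives_bimodal_truth(self):
        img = generate_tem_image([(44.0, 5.0, 0.5), (81.0, 5.0, 0.5)],
                                 TEMGeometry(), 0.0, seed=1)
        th = img.truth["thickness_nm"]
        low = np.mean(np.abs(th - 44) < 15)
        high = np.mean(np.abs(th - 81) < 15)
        mid = np.mean((th > 59) & (th < 66))
        assert low > 0.3 and high > 0.3 and mid < 0.1

    def test_too_coarse_scale_raises(self):
        with pytest.raises(ValueError):
            generate_tem_image([(6.0, 0.0, 1.0)],
                               TEMGeometry(nm_per_px=4.0), 0.0, seed=0)


class TestBiodistribution:
    def _traj(self):
        from capkit.pk import PKTrajectory
        t = np.linspace(0, 72, 5)
        return PKTrajectory(times=t, blood=np.full(5, 1e4),
                            peripheral=np.full(5, 2e5),
                            tumors=np.full((1, 5), 4e7),
                            cap=np.zeros(5))

    def test_noiseless_identity_and_mass_scaling(self):
        traj = self._traj()
        df = generate_biodistribution(traj, {"blood": 2.0, "tumor_0": 0.5},
                                      0.0, seed=0)
        vals = dict(zip(df["organ"], df["cfu_per_g"]))
        assert vals["blood"] == pytest.approx(1e4 / 2.0)
        assert vals["tumor_0"] == pytest.approx(4e7 / 0.5)
        df2 = generate_biodistribution(traj, {"tumor_0": 1.0}, 0.0, seed=0)
        assert df2["cfu_per_g"].iloc[0] == pytest.approx(vals["tumor_0"] / 2)

    def test_geometric_mean_close_to_noiseless(self):
        traj = self._traj()
        vals = np.array([
            generate_biodistribution(traj, {"peripheral": 1.5}, 0.3,
                                     seed=s)["cfu_per_g"].iloc[0]
            for s in range(500)])
        noiseless = 2e5 / 1.5
        # mean-one lognormal: arithmetic mean is unbiased
        assert abs(vals.mean() - noiseless) / noiseless < 0.05
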