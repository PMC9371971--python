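"""Compartmental PK: closed forms, conservation, orderings, translocation."""

import numpy as np
import pytest

from capkit.cap import CapKinetics, InductionSchedule
from capkit.pk import (PKParams, PKTrajectory, build_scenario, simulate,
                       translocation_fraction, tumor_specificity)
from capkit.pipeline import default_config, params_from_config

KIN = CapKinetics()
GRID = np.linspace(0.0, 72.0, 145)


def _params(**over):
    base = dict(k_clear=20.0, p_min=0.1, k_mps=0.25, delta_p=0.3,
                k_entry=0.03, k_escape=0.0, r_t=0.1, cap_k=1e9, n_tumors=2)
    base.update(over)
    return PKParams(**base)


class TestSimulate:
    def test_null_dynamics_all_rates_zero(self):
        p = _params(k_clear=0, p_min=1.0, k_mps=0, delta_p=0, k_entry=0,
                    k_escape=0, r_t=0)
        sc = build_scenario("iv", 1e6, "none", None, 72.0)
        traj = simulate(p, sc, KIN, GRID)
        assert np.allclose(traj.blood, 1e6, rtol=1e-9)
        assert np.allclose(traj.peripheral, 0.0)
        assert np.allclose(traj.tumors, 0.0)

    def test_blood_only_matches_exponential_closed_form(self):
        p = _params(k_clear=2.0, k_mps=0, k_entry=0, k_escape=0, delta_p=0,
                    r_t=0)
        sc = build_scenario("iv", 5e6, "none", None, 6.0)
        grid = np.linspace(0, 6, 97)
        traj = simulate(p, sc, KIN, grid)
        expected = 5e6 * np.exp(-2.0 * grid)  # stays above ~30 CFU
        rel = np.abs(traj.blood - expected) / expected
        assert np.max(rel) < 1e-6

    def test_mass_conservation_without_elimination_or_growth(self):
        p = _params(k_clear=0, p_min=1.0, delta_p=0, r_t=0, k_escape=0.05)
        sc = build_scenario("iv", 1e7, "none", None, 72.0)
        traj = simulate(p, sc, KIN, GRID)
        total = traj.blood + traj.peripheral + traj.tumors.sum(axis=0)
        assert np.max(np.abs(total - 1e7)) / 1e7 < 1e-8

    def test_protection_ordering_pointwise(self):
        p = _params()
        trajs = {}
        for mode in ("none", "transient", "static"):
            sc = build_scenario("iv", 5e6, mode, None, 72.0)
            trajs[mode] = simulate(p, sc, KIN, GRID)
        tol = 1e-9 * 5e6
        assert np.all(trajs["static"].blood >= trajs["transient"].blood - tol)
        assert np.all(trajs["transient"].blood >= trajs["none"].blood - tol)

    def test_it_route_seeds_treated_tumor(self):
        p = _params(k_escape=0.01)
        sc = build_scenario("it", 1e6, "none", None, 72.0, treated_tumor=0)
        traj = simulate(p, sc, KIN, GRID)
        assert traj.tumors[0, 0] == pytest.approx(1e6)
        assert traj.blood[0] == 0.0


class TestSpecificity:
    def _manual(self, b, per, tumors):
        t = np.array([0.0, 72.0])
        return PKTrajectory(times=t, blood=np.full(2, b),
                            peripheral=np.full(2, per),
                            tumors=np.tile(np.asarray(tumors)[:, None], 2),
                            cap=np.zeros(2))

    def test_degenerate_all_in_tumor(self):
        traj = self._manual(0.0, 0.0, [1e7])
        assert tumor_specificity(traj, 72.0) == pytest.approx(1e7 / 1.0)

    def test_equal_tumor_and_blood_is_about_one(self):
        traj = self._manual(1e7, 0.0, [1e7])
        assert tumor_specificity(traj, 72.0) == pytest.approx(1.0, rel=1e-6)

    def test_transient_beats_static_and_none_under_defaults(self):
        params = params_from_config(default_config(0))
        s = {}
        for mode in ("none", "static", "transient"):
            sc = build_scenario("iv", 5e6, mode, None, 72.0)
            s[mode] = tumor_specificity(simulate(params, sc, KIN, GRID), 72.0)
        assert s["transient"] > s["static"]
        assert s["transient"] > s["none"]


class TestTranslocation:
    def test_fraction_symmetric_and_no_route(self):
        t = np.array([0.0, 72.0])
        traj = PKTrajectory(times=t, blood=np.zeros(2),
                            peripheral=np.zeros(2),
                            tumors=np.array([[1e5, 1e5], [1e5, 1e5]]),
                            cap=np.zeros(2))
        assert translocation_fraction(traj, 0, 72.0) == {1: 1.0}
        p = _params(k_entry=0.0, k_escape=0.0)
        sc = build_scenario("it", 1e6, "none", None, 72.0)
        traj2 = simulate(p, sc, KIN, GRID)
        assert translocation_fraction(traj2, 0, 72.0)[1] == 0.0

    def test_in_situ_induction_increases_translocation(self):
        rng = np.random.default_rng(1)
        sched = InductionSchedule.step(24.0, 72.0, 1e4)
        for _ in range(10):
            p = _params(k_clear=rng.uniform(5, 30),
                        p_min=rng.uniform(0.02, 0.5),
                        k_escape=10 ** rng.uniform(-3, -1),
                        k_entry=10 ** rng.uniform(-2.5, -1))
            frac = {}
            for mode, sch in (("none", None), ("in_situ", sched)):
                sc = build_scenario("it", 1e6, mode, sch, 72.0)
                frac[mode] = translocation_fraction(
                    simulate(p, sc, KIN, GRID), 0, 72.0)[1]
            assert frac["in_situ"] > frac["none"]

    def test_single_tumor_raises(self):
        p = _params(n_tumors=1)
        sc = build_scenario("it", 1e6, "none", None, 72.0)
        traj = simulate(p, sc, KIN, GRID)
        with pytest.raises(ValueError):
            translocation_fraction(traj, 0, 72.0)


class TestBuildScenario:
    def test_zero_dose_raises(self):
        with pytest.raises(ValueError):
            build_scenario("iv", 0.0, "none", None, 72.0)

    def test_in_situ_without_schedule_raises(self):
        with pytest.raises(ValueError):
            build_scenario("it", 1e6, "in_situ", None, 72.0)

    def test_in_situ_on_at_zero_warns_but_allowed(self):
        sched = InductionSchedule.constant(10.0, 72.0)
        with pytest.warns(UserWarning):
            sc = build_scenario("it", 1e6, "in_situ", sched, 72.0)
        assert sc.cap_mode == "in_situ"

    def test_step_schedule_boundaries(self):
        sched = InductionSchedule.step(24.0, 72.0, 1e4)
        assert sched.bounds == (0.0, 24.0, 72.0)
        assert sched.concentration_at(12.0) == 0.0
        assert sched.concentration_at(30.0) == 1e4
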