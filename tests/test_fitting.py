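import numpy as np
import pytest
from scipy import stats

import ikrfit as ik
from ikrfit.cmaes import default_population_size, minimize_cmaes
from ikrfit.fitting import (
    FitConfig,
    check_rate_bounds,
    conductance_bounds,
    objective,
    population_size,
    sample_initial_guess,
)
from ikrfit.models import RateForm, RateKind

E_NERNST = -89.85


class TestCmaes:
    def test_minimizes_sphere(self):
        res = minimize_cmaes(lambda x: float(np.sum(x ** 2)), np.full(8, 3.0),
                             sigma0=0.5, seed=1, maxevals=20_000)
        assert res.fun < 1e-12

    def test_minimizes_rosenbrock(self):
        def rosen(x):
            return float(np.sum(100 * (x[1:] - x[:-1] ** 2) ** 2
                                + (1 - x[:-1]) ** 2))
        res = minimize_cmaes(rosen, np.zeros(5), sigma0=0.5, seed=2,
                             maxevals=40_000)
        assert res.x == pytest.approx(np.ones(5), abs=1e-4)

    def test_seeded_runs_are_identical(self):
        f = lambda x: float(np.sum((x - 1.5) ** 2))
        a = minimize_cmaes(f, np.zeros(3), seed=7, maxevals=2000)
        b = minimize_cmaes(f, np.zeros(3), seed=7, maxevals=2000)
        assert np.array_equal(a.x, b.x) and a.fun == b.fun

    def test_population_heuristic(self):
        assert default_population_size(1) == 4
        assert default_population_size(9) == int(np.floor(4 + 3 * np.log(9)))


class TestObjective:
    def test_zero_at_generating_parameters(self, beattie_sim_10ms, staircase_10ms):
        m, p, sim = beattie_sim_10ms
        sse = objective(m, p, staircase_10ms, sim.current, E_NERNST)
        assert sse <= 1e-8 * np.sum(sim.current ** 2)

    def test_equals_hand_computed_residual_sum(self, beattie_sim_10ms,
                                               staircase_10ms):
        m, p, sim = beattie_sim_10ms
        rng = np.random.default_rng(0)
        z = sim.current + rng.normal(0, 20.0, len(sim.current))
        expected = float(np.sum((sim.current - z) ** 2))
        assert objective(m, p, staircase_10ms, z, E_NERNST) == pytest.approx(
            expected, rel=1e-9)

    def test_invalid_parameters_give_infinite_objective(self, staircase_10ms):
        m = ik.build_model("COI")
        bad = np.full(m.total_params, -1.0)
        with pytest.warns(UserWarning, match="simulation failed"):
            val = objective(m, bad, staircase_10ms,
                            np.zeros(len(staircase_10ms.times())), E_NERNST)
        assert val == np.inf


class TestRateBounds:
    def test_tiny_constant_rate_fails_lower_bound(self):
        form = RateForm(RateKind.POS_EXP, 0, 1)
        assert not check_rate_bounds(form, 1e-7, 0.0)

    def test_moderate_positive_rate_passes(self):
        # kmax = exp(0.1 * 60) = e^6 ~ 403
        assert check_rate_bounds(RateForm(RateKind.POS_EXP, 0, 1), 1.0, 0.1)

    def test_fast_negative_rate_fails_upper_bound(self):
        # kmax = 1e3 * exp(0.04 * 120) ~ 1.2e5 > 1e5
        assert not check_rate_bounds(RateForm(RateKind.NEG_EXP, 0, 1), 1e3, 0.04)


class TestConductanceBounds:
    def _trace(self, protocol, scale=1.0):
        m = ik.build_model("Beattie")
        p = ik.default_parameters(m)
        sim = ik.simulate_current(m, p, protocol, E_Kr=E_NERNST)
        return ik.SweepTrace("w", protocol.name, 1, "pre", sim.times,
                             scale * sim.current), p[m.conductance_index]

    def test_doubling_current_doubles_bounds(self, staircase_10ms):
        tr1, _ = self._trace(staircase_10ms)
        tr2, _ = self._trace(staircase_10ms, scale=2.0)
        lo1, hi1 = conductance_bounds(tr1, staircase_10ms, E_NERNST)
        lo2, hi2 = conductance_bounds(tr2, staircase_10ms, E_NERNST)
        assert (lo2, hi2) == pytest.approx((2 * lo1, 2 * hi1))

    def test_zero_trace_degenerates_with_warning(self, staircase_10ms):
        t = staircase_10ms.times()
        tr = ik.SweepTrace("w", "d1", 1, "pre", t, np.zeros(len(t)))
        with pytest.warns(UserWarning, match="zero current"):
            lo, hi = conductance_bounds(tr, staircase_10ms, E_NERNST)
        assert lo == 0.0 and hi == np.inf

    def test_true_conductance_inside_bounds(self, staircase_10ms):
        tr, g_true = self._trace(staircase_10ms)
        lo, hi = conductance_bounds(tr, staircase_10ms, E_NERNST)
        assert lo < g_true < hi


class TestPopulationSize:
    def test_heuristic_values(self):
        assert population_size(1) == 4
        assert population_size(9) == 10

    def test_wang_override(self):
        assert population_size(15, override=50) == 50


class TestInitialGuesses:
    def test_all_draws_satisfy_rate_bounds(self):
        m = ik.build_model("COI")
        cfg = FitConfig()
        forms = {(t.rate.A_index, t.rate.b_index): t.rate for t in m.transitions}
        for s in range(200):
            theta = sample_initial_guess(m, cfg, (1e-3, 1e3), seed=s)
            for form in forms.values():
                b = 0.0 if form.b_index is None else theta[form.b_index]
                assert check_rate_bounds(form, theta[form.A_index], b, cfg)
            assert 1e-3 <= theta[-1] <= 1e3 or 1e-7 <= theta[-1] <= 10.0

    def test_same_seed_same_guess(self):
        m = ik.build_model("Wang")
        cfg = FitConfig()
        a = sample_initial_guess(m, cfg, (0.1, 100.0), seed=9)
        b = sample_initial_guess(m, cfg, (0.1, 100.0), seed=9)
        assert np.array_equal(a, b)

    def test_log10_prior_is_uniform(self):
        """With bounds disabled the raw sampler is log10-uniform on (-7, 1)."""
        m = ik.build_model("COI")
        cfg = FitConfig(rate_bound_lo=1e-300, rate_bound_hi=1e300)
        draws = np.concatenate([
            sample_initial_guess(m, cfg, (1e-7, 10.0), seed=s)[:m.n_kinetic_params]
            for s in range(400)
        ])
        ks = stats.kstest(np.log10(draws), stats.uniform(-7, 8).cdf)
        assert ks.pvalue > 0.01

    def test_pathological_bounds_error(self):
        m = ik.build_model("COI")
        cfg = FitConfig(rate_bound_lo=0.99e5, rate_bound_hi=1e5)
        with pytest.raises(RuntimeError, match="pathological|feasible"):
            sample_initial_guess(m, cfg, (1.0, 2.0), seed=1)


class TestFitSweep:
    def test_conductance_only_recovery_is_fast_and_exact(self, staircase_10ms):
        """A short CMA run plus polish recovers g when kinetics are known."""
        m = ik.build_model("COI")
        p = ik.default_parameters(m)
        sim = ik.simulate_current(m, p, staircase_10ms, E_Kr=E_NERNST)
        tr = ik.SweepTrace("w", "d1", 1, "pre", sim.times, sim.current,
                           V_off=0.0)
        cfg = FitConfig(n_repeats=2, maxevals=2500, seed=5)
        fr = ik.fit_sweep(m, tr, staircase_10ms, cfg, E_Kr=E_NERNST)
        assert fr.rmse <= fr.repeats["rmse"].min() + 1e-12
        assert fr.sse == pytest.approx(
            objective(m, fr.params, staircase_10ms, sim.current, E_NERNST),
            rel=1e-9)
        # fitted parameters respect every bound
        for t in m.transitions:
            b = 0.0 if t.rate.b_index is None else fr.params[t.rate.b_index]
            assert check_rate_bounds(t.rate, fr.params[t.rate.A_index], b, cfg)

    def test_fit_never_beats_itself_on_training_objective(self, staircase_10ms):
        """RMSE at the estimate is <= RMSE at the true parameters."""
        m = ik.build_model("COI")
        p = ik.default_parameters(m)
        sim = ik.simulate_current(m, p, staircase_10ms, E_Kr=E_NERNST)
        rng = np.random.default_rng(2)
        z = sim.current + rng.normal(0, 20.0, len(sim.current))
        tr = ik.SweepTrace("w", "d1", 1, "pre", sim.times, z, V_off=0.0)
        cfg = FitConfig(n_repeats=2, maxevals=2500, seed=6)
        fr = ik.fit_sweep(m, tr, staircase_10ms, cfg, E_Kr=E_NERNST)
        sse_truth = objective(m, p, staircase_10ms, z, E_NERNST)
        assert fr.sse <= sse_truth
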