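import numpy as np
import pytest

import ikrfit as ik
from ikrfit.postprocess import (
    PostprocessError,
    QCCriteria,
    compute_voltage_offset,
    drug_subtract,
    estimate_noise_sd,
    fit_leak,
    infer_reversal,
    leak_subtract,
    postprocess_pair,
    qc_filter,
)

E_NERNST = -89.85


def leak_trace(protocol, g_L, E_L, noise_sd=0.0, seed=0):
    t = protocol.times()
    v = protocol.voltage_at(t)
    i = g_L * (v - E_L)
    if noise_sd:
        i = i + np.random.default_rng(seed).normal(0, noise_sd, len(t))
    return ik.SweepTrace("w", protocol.name, 1, "pre", t, i)


@pytest.fixture(scope="module")
def proto():
    return ik.staircase_like(sample_interval=1.0)


@pytest.fixture(scope="module")
def clean_pair(proto):
    """Noiseless pre/post sweep pair with leak, offset, and known truth."""
    m = ik.build_model("Beattie")
    base = ik.default_parameters(m)
    truth = ik.WellGroundTruth(
        well="w", params={"d1": base}, leak=ik.LeakModel(1.2, -8.0),
        V_off=3.0, noise_sd=0.0, E_Kr=E_NERNST,
    )
    pre = ik.generate_sweep(truth, m, proto, "pre", seed=1)
    post = ik.generate_sweep(truth, m, proto, "post", seed=2)
    ikr = ik.simulate_current(m, base, proto, E_Kr=E_NERNST,
                              V_off=truth.V_off).current
    return truth, pre, post, ikr


class TestLeakFit:
    def test_exact_on_pure_linear_leak(self, proto):
        leak = fit_leak(leak_trace(proto, 1.0, -10.0), proto)
        assert leak.g_L == pytest.approx(1.0, abs=1e-9)
        assert leak.E_L == pytest.approx(-10.0, abs=1e-9)

    def test_zero_current_flags_degenerate(self, proto):
        leak = fit_leak(leak_trace(proto, 0.0, 0.0), proto)
        assert leak.g_L == 0.0 and leak.E_L == 0.0 and leak.degenerate

    def test_noisy_recovery_within_monte_carlo_error(self, proto):
        g_true = 1.0
        ests = [fit_leak(leak_trace(proto, g_true, -10.0, 20.0, seed=s), proto).g_L
                for s in range(100)]
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / 10.0
        assert abs(ests.mean() - g_true) <= 3 * se

    def test_short_window_rejected(self, proto):
        tr = leak_trace(proto, 1.0, 0.0)
        coarse = ik.staircase_like(sample_interval=300.0)
        with pytest.raises(PostprocessError, match="3 samples"):
            fit_leak(ik.SweepTrace("w", "d1", 1, "pre", coarse.times(),
                                   np.zeros(len(coarse.times()))), coarse)


class TestLeakSubtract:
    def test_zero_leak_is_identity(self, proto):
        tr = leak_trace(proto, 1.0, -10.0)
        out = leak_subtract(tr, ik.LeakModel(0.0, 0.0), proto)
        assert out.current == pytest.approx(tr.current)

    def test_residual_vanishes_on_pure_leak(self, proto):
        tr = leak_trace(proto, 0.8, 5.0)
        out = leak_subtract(tr, fit_leak(tr, proto), proto)
        assert np.abs(out.current).max() <= 1e-9

    def test_ramp_residual_mean_is_zero(self, proto):
        tr = leak_trace(proto, 0.8, 5.0, noise_sd=10.0, seed=3)
        out = leak_subtract(tr, fit_leak(tr, proto), proto)
        mask = proto.section_mask(ik.SectionTag.LEAK_RAMP, ramps_only=True)
        assert abs(out.current[mask].mean()) <= 1e-8


class TestDrugSubtract:
    def test_identical_sweeps_cancel(self, proto):
        tr = leak_trace(proto, 1.0, 0.0)
        assert np.all(drug_subtract(tr, tr).current == 0.0)

    def test_noiseless_pair_recovers_pure_ikr_exactly(self, clean_pair):
        _, pre, post, ikr = clean_pair
        # identical true leak pre/post cancels in the raw difference
        assert drug_subtract(pre, post).current == pytest.approx(ikr, abs=1e-9)

    def test_grid_mismatch_rejected(self, proto):
        a = leak_trace(proto, 1.0, 0.0)
        short = ik.SweepTrace("w", proto.name, 1, "post", a.times[:-10],
                              a.current[:-10])
        with pytest.raises(PostprocessError, match="grid"):
            drug_subtract(a, short)

    def test_noise_variance_doubles(self, proto):
        t = proto.times()
        rng = np.random.default_rng(4)
        mk = lambda seed: ik.SweepTrace("w", proto.name, 1, "pre", t,
                                        rng.normal(0, 20, len(t)))
        out = drug_subtract(mk(1), mk(2))
        assert np.var(out.current) == pytest.approx(2 * 400, rel=0.1)


class TestReversalInference:
    def test_noiseless_accuracy_half_millivolt(self, clean_pair, proto):
        truth, pre, post, _ = clean_pair
        corr = postprocess_pair(pre, post, proto, E_NERNST)
        # zero crossing sits where V_cmd + V_off = E_Kr
        assert corr.E_obs == pytest.approx(E_NERNST - truth.V_off, abs=0.5)

    def test_offset_shifts_observed_reversal_oppositely(self, proto):
        m = ik.build_model("Beattie")
        base = ik.default_parameters(m)
        obs = {}
        for v_off in (0.0, 5.0):
            truth = ik.WellGroundTruth(
                well="w", params={"d1": base}, leak=ik.LeakModel(0, 0),
                V_off=v_off, noise_sd=0.0, E_Kr=E_NERNST)
            tr = ik.generate_sweep(truth, m, proto, "pre", seed=1)
            obs[v_off] = infer_reversal(tr, proto)
        # tolerance reflects the quartic-fit bias of the estimator
        assert obs[5.0] - obs[0.0] == pytest.approx(-5.0, abs=0.5)

    def test_positive_current_has_no_root(self, proto):
        t = proto.times()
        tr = ik.SweepTrace("w", proto.name, 1, "pre", t, np.full(len(t), 50.0))
        with pytest.raises(PostprocessError, match="crossing"):
            infer_reversal(tr, proto)


class TestVoltageOffset:
    def test_printed_formula(self):
        assert compute_voltage_offset(-90.0, -90.0) == 0.0
        assert compute_voltage_offset(-85.0, -90.0) == -5.0

    def test_end_to_end_recovery_within_one_millivolt(self, clean_pair, proto):
        truth, pre, post, _ = clean_pair
        corr = postprocess_pair(pre, post, proto, E_NERNST)
        assert corr.V_off == pytest.approx(truth.V_off, abs=1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            compute_voltage_offset(np.nan, -90.0)


class TestNoiseEstimate:
    def test_zero_on_noiseless_trace(self, clean_pair, proto):
        _, pre, post, _ = clean_pair
        corr = postprocess_pair(pre, post, proto, E_NERNST)
        assert corr.sigma_hat <= 1e-9

    def test_recovers_requested_sigma(self, proto):
        t = proto.times()
        hits = 0
        for s in range(100):
            cur = np.random.default_rng(s).normal(0, 20.0, len(t))
            est = estimate_noise_sd(
                ik.SweepTrace("w", proto.name, 1, "pre", t, cur), proto)
            hits += 18.0 <= est <= 22.0
        assert hits >= 95

    def test_invariant_to_constant_offset(self, proto):
        t = proto.times()
        cur = np.random.default_rng(9).normal(0, 20.0, len(t))
        a = estimate_noise_sd(ik.SweepTrace("w", "d1", 1, "pre", t, cur), proto)
        b = estimate_noise_sd(ik.SweepTrace("w", "d1", 1, "pre", t, cur + 123.0),
                              proto)
        assert a == pytest.approx(b)

    def test_short_hold_rejected(self):
        leading, trailing = ik.make_scaffold({"hold_start": 5.0})
        proto = ik.VoltageProtocol("p", leading + trailing, sample_interval=1.0)
        t = proto.times()
        with pytest.raises(PostprocessError, match="10 samples"):
            estimate_noise_sd(ik.SweepTrace("w", "p", 1, "pre", t,
                                            np.zeros(len(t))), proto)


class TestQC:
    def _corrected(self, **tweaks):
        """Four fabricated corrected staircase sweeps for one well."""
        proto = ik.staircase_like(sample_interval=10.0)
        t = proto.times()
        out = {}
        for s in range(1, 5):
            tr = ik.SweepTrace("w", "d1", s, "pre", t,
                               np.sin(t / 500.0) * 100.0)
            tr.sigma_hat = tweaks.get("sigma", 10.0)
            tr.E_obs = tweaks.get("E_obs", E_NERNST)
            tr.V_off = E_NERNST - tr.E_obs
            tr.postdrug_ratio = tweaks.get("ratio", 0.1)
            if tweaks.get("drift") and s == 4:
                tr.current = tr.current * 2.0
            out[("w", "d1", s)] = tr
        return out

    def test_clean_well_passes(self):
        passing, flags = qc_filter(self._corrected(), E_NERNST)
        assert passing == ["w"]
        assert not flags.any().any()

    def test_reversal_violation_flags_only_that_criterion(self):
        passing, flags = qc_filter(self._corrected(E_obs=E_NERNST - 30.0),
                                   E_NERNST)
        assert passing == []
        assert flags.loc["w", "reversal"]
        assert not flags.loc["w", ["noise", "staircase_drift",
                                   "postdrug_ratio"]].any()

    def test_staircase_drift_detected(self):
        passing, flags = qc_filter(self._corrected(drift=True), E_NERNST)
        assert flags.loc["w", "staircase_drift"] and passing == []

    def test_missing_staircase_repeats_autofail(self):
        corr = self._corrected()
        corr.pop(("w", "d1", 4))
        passing, flags = qc_filter(corr, E_NERNST)
        assert flags.loc["w", "missing_staircase"] and passing == []

    def test_loosening_thresholds_is_monotone(self):
        corr = self._corrected(sigma=45.0, ratio=0.4)
        tight = QCCriteria()
        loose = QCCriteria(max_sigma=100.0, max_staircase_drift=0.5,
                           max_Eobs_deviation=30.0, max_postdrug_ratio=1.0)
        passed_tight, _ = qc_filter(corr, E_NERNST, tight)
        passed_loose, _ = qc_filter(corr, E_NERNST, loose)
        assert set(passed_tight) <= set(passed_loose)

    def test_injected_drifting_leak_well_fails_drift(self):
        proto = ik.staircase_like(sample_interval=10.0)
        cfg = ik.SyntheticConfig(
            model_name="COI", wells=("good", "bad"), protocols={"d1": proto},
            failures={"bad": "drift_leak"},
        )
        ds = ik.generate_dataset(cfg, seed=5)
        corrected, raw = {}, {}
        for well in ds.design.wells:
            for e in ds.design.sweeps("pre"):
                pre = ds.trace(well, e.protocol, e.sweep, "pre")
                post = ds.trace(well, e.protocol, e.sweep, "post")
                raw[(well, e.protocol, e.sweep)] = pre
                corrected[(well, e.protocol, e.sweep)] = postprocess_pair(
                    pre, post, proto, ds.E_Kr)
        passing, flags = qc_filter(corrected, ds.E_Kr, raw=raw)
        assert "good" in passing
        assert flags.loc["bad", "staircase_drift"]
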