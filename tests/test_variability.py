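import numpy as np
import pandas as pd
import pytest

import ikrfit as ik
from ikrfit.fitting import FitResult
from ikrfit.synthetic import generate_well_params, kinetic_slot_kinds
from ikrfit.variability import (
    build_design_matrices,
    fit_linear_model,
    lld,
    lld_table,
    transform_estimates,
)


def make_fit(well, protocol, sweep, params, model_name="Beattie"):
    return FitResult(well=well, protocol=protocol, sweep=sweep,
                     model_name=model_name, params=np.asarray(params, float),
                     sse=0.0, rmse=0.0, repeats=pd.DataFrame(),
                     E_Kr=-89.85, V_off=0.0)


def synthetic_table(well_sd, proto_sd, noise_sd, seed, n_wells=8,
                    model_name="Beattie"):
    """Estimate table built from the generator's ground-truth parameters
    plus small Gaussian estimation error, mimicking per-sweep fits."""
    m = ik.build_model(model_name)
    base = ik.default_parameters(m)
    wells = [f"w{i}" for i in range(n_wells)]
    protocols = [f"d{i}" for i in range(1, 12)]  # 11 fitting protocols
    params, _ = generate_well_params(base, m, wells, protocols,
                                     well_sd, proto_sd, seed=seed)
    fits = []
    for w in wells:
        for d in protocols:
            sweeps = (1, 2, 3, 4) if d == "d1" else (1,)
            for s in sweeps:
                fits.append(make_fit(w, d, s, params[(w, d)], model_name))
    table = transform_estimates(fits, m)
    rng = np.random.default_rng([seed, 99])
    return table + rng.normal(0, noise_sd, size=table.shape)


class TestTransform:
    def test_log_prefactors_and_identity_exponents(self):
        m = ik.build_model("Beattie")
        p = np.ones(m.total_params)
        table = transform_estimates([make_fit("w", "d1", 1, p)], m)
        kinds = kinetic_slot_kinds(m)
        row = table.iloc[0].to_numpy()
        assert np.all(row[[i for i, k in enumerate(kinds) if k == "A"]] == 0.0)
        assert np.all(row[[i for i, k in enumerate(kinds) if k == "b"]] == 1.0)

    def test_round_trip_to_machine_precision(self):
        m = ik.build_model("COI")
        p = ik.default_parameters(m)
        table = transform_estimates([make_fit("w", "d1", 1, p, "COI")], m)
        kinds = kinetic_slot_kinds(m)
        for i, k in enumerate(kinds):
            if k == "A":
                assert np.exp(table.iloc[0, i]) == pytest.approx(p[i], rel=1e-14)

    def test_conductance_column_dropped(self):
        m = ik.build_model("Beattie")
        table = transform_estimates(
            [make_fit("w", "d1", 1, ik.default_parameters(m))], m)
        assert table.shape[1] == 8  # nine parameters minus g

    def test_mixed_models_rejected(self):
        m = ik.build_model("Beattie")
        fits = [make_fit("w", "d1", 1, ik.default_parameters(m)),
                make_fit("w", "d2", 1, np.ones(9), model_name="COI")]
        with pytest.raises(ValueError, match="same model"):
            transform_estimates(fits, m)


class TestDesignMatrices:
    def test_expanded_effects_sum_to_zero(self):
        labels = [(w, d) for w in "abc" for d in ("d1", "d2", "d3", "d4")]
        X_w, X_d, wl, dl = build_design_matrices(labels)
        # effect coding: column sums over a balanced design vanish
        assert np.abs(X_w.sum(axis=0)).max() == 0
        assert np.abs(X_d.sum(axis=0)).max() == 0

    def test_crossed_design_rank(self):
        labels = [(w, d) for w in "abc" for d in ("d1", "d2", "d3", "d4")]
        X_w, X_d, wl, dl = build_design_matrices(labels)
        X = np.hstack([np.ones((len(labels), 1)), X_d, X_w])
        assert np.linalg.matrix_rank(X) == 1 + (3 - 1) + (4 - 1)

    def test_single_well_degenerates_to_protocol_model(self):
        m = ik.build_model("COI")
        p = ik.default_parameters(m)
        fits = [make_fit("w", f"d{i}", 1, p * (1 + 0.01 * i), "COI")
                for i in range(1, 4)]
        table = transform_estimates(fits, m)
        full = fit_linear_model(table, "Mwd")
        md = fit_linear_model(table, "Md")
        assert full.loglik == pytest.approx(md.loglik)


class TestLinearModel:
    def test_noiseless_effects_recovered_exactly(self):
        table = synthetic_table(0.2, 0.1, noise_sd=0.0, seed=1, n_wells=4)
        fit = fit_linear_model(table, "Mwd")
        assert np.abs(fit.residuals).max() <= 1e-9
        assert np.abs(fit.beta_w.sum(axis=0)).max() <= 1e-10
        assert np.abs(fit.beta_d.sum(axis=0)).max() <= 1e-10

    def test_nested_likelihood_monotonicity(self):
        table = synthetic_table(0.1, 0.05, noise_sd=0.05, seed=2, n_wells=4)
        ll = {v: fit_linear_model(table, v).loglik
              for v in ("M0", "Mw", "Md", "Mwd")}
        assert ll["Mwd"] >= ll["Mw"] >= ll["M0"]
        assert ll["Mwd"] >= ll["Md"] >= ll["M0"]

    def test_well_effects_recovered_within_error(self):
        """8 wells x 14 sweeps, matching the study's post-QC shape."""
        m = ik.build_model("Beattie")
        base = ik.default_parameters(m)
        wells = [f"w{i}" for i in range(8)]
        protocols = [f"d{i}" for i in range(1, 12)]
        params, eff = generate_well_params(base, m, wells, protocols,
                                           0.3, 0.05, seed=3)
        noise_sd = 0.02
        fits = []
        for w in wells:
            for d in protocols:
                for s in (1, 2, 3, 4) if d == "d1" else (1,):
                    fits.append(make_fit(w, d, s, params[(w, d)]))
        table = transform_estimates(fits, m)
        rng = np.random.default_rng(30)
        table = table + rng.normal(0, noise_sd, size=table.shape)
        fit = fit_linear_model(table, "Mwd")
        kinds = kinetic_slot_kinds(m)
        a_cols = [i for i, k in enumerate(kinds) if k == "A"]
        n_per_well = len(table) // len(wells)
        se = 2 * noise_sd / np.sqrt(n_per_well)
        est = fit.beta_w.to_numpy()[:, a_cols]
        assert np.abs(est - eff["well"][:, a_cols]).max() <= 2 * max(se, 0.01)

    def test_loglik_invariant_to_row_permutation(self):
        table = synthetic_table(0.1, 0.05, noise_sd=0.05, seed=4, n_wells=3)
        perm = table.sample(frac=1.0, random_state=5)
        assert fit_linear_model(perm, "Mwd").loglik == pytest.approx(
            fit_linear_model(table, "Mwd").loglik)

    def test_unknown_variant_rejected(self):
        table = synthetic_table(0.1, 0.05, 0.05, seed=6, n_wells=3)
        with pytest.raises(ValueError, match="variant"):
            fit_linear_model(table, "Mx")


class TestLld:
    def test_identical_likelihoods_give_zero(self):
        # with one well the full model degenerates to Md: the nested
        # pair has identical likelihoods and the difference is exactly 0
        m = ik.build_model("COI")
        p = ik.default_parameters(m)
        fits = [make_fit("w", f"d{i}", 1, p * (1 + 0.01 * i), "COI")
                for i in range(1, 5)]
        table = transform_estimates(fits, m)
        full = fit_linear_model(table, "Mwd")
        red = fit_linear_model(table, "Md")
        assert lld(full, red) == 0.0

    def test_non_nested_pair_rejected(self):
        table = synthetic_table(0.1, 0.05, 0.05, seed=8, n_wells=3)
        mw = fit_linear_model(table, "Mw")
        md = fit_linear_model(table, "Md")
        with pytest.raises(ValueError, match="nested"):
            lld(mw, md)

    def test_always_nonnegative_for_nested_pairs(self):
        for seed in range(5):
            table = synthetic_table(0.05, 0.05, 0.1, seed=seed, n_wells=4)
            stats = lld_table(table)
            assert stats["LLD_w"] >= -1e-8
            assert stats["LLD_d"] >= -1e-8

    def test_strong_well_effects_inflate_lld_w(self):
        """Strong vs absent well effects: LLD(-w) separates by >= 10x."""
        strong, zero = [], []
        for seed in range(10):
            strong.append(lld_table(
                synthetic_table(0.5, 0.02, 0.05, seed=seed))["LLD_w"])
            zero.append(lld_table(
                synthetic_table(0.0, 0.02, 0.05, seed=seed))["LLD_w"])
        assert np.median(strong) >= 10 * max(np.median(zero), 1e-12)

    def test_well_only_effects_rank_lld_w_above_lld_d(self):
        stats = lld_table(synthetic_table(0.5, 0.0, 0.05, seed=11))
        assert stats["LLD_w"] > 10 * stats["LLD_d"]
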