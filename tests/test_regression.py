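"""OLS fitting of LFER sensitivities, model comparison, and decomposition."""

import warnings

import numpy as np
import pytest

from strainlfer import (
    CollinearityError,
    GeneratorSpec,
    LFERParameters,
    ReactionRecord,
    UnphysicalParameterWarning,
    compare_models,
    decompose_vs_reference,
    fit_lfer,
    generate,
    predict_barriers,
    summary_table,
)
from strainlfer.regression import loo_diagnostics


def noiseless_table(seed=1, **kw):
    spec = GeneratorSpec(noise_sigma=0.0, seed=seed, **kw)
    return generate(spec), spec


class TestFitLfer:
    def test_exact_recovery_on_noiseless_data(self):
        table, spec = noiseless_table(alpha=0.5, beta=-10.0, intercept=40.0)
        fit = fit_lfer(table.records, descriptor="n3")
        assert fit.params.alpha == pytest.approx(spec.alpha, abs=1e-10)
        assert fit.params.beta == pytest.approx(spec.beta, abs=1e-10)
        assert fit.params.intercept == pytest.approx(spec.intercept, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_exact_recovery_chi_nbo(self):
        table, spec = noiseless_table(
            alpha=0.51, beta=-192.4, intercept=25.0, chi_distribution="uniform"
        )
        fit = fit_lfer(table.records, descriptor="chi_nbo")
        assert fit.params.beta == pytest.approx(-192.4, abs=1e-8)

    def test_zero_descriptor_column_is_collinear(self):
        records = [
            ReactionRecord(id=f"r{i}", dH_r=d, dH_act=40 + 0.5 * d, n3=0)
            for i, d in enumerate([-50.0, -30.0, -10.0, -20.0])
        ]
        with pytest.raises(CollinearityError, match="n3"):
            fit_lfer(records, descriptor="n3")

    def test_descriptor_proportional_to_driving_force_is_collinear(self):
        records = [
            ReactionRecord(id=f"r{i}", dH_r=d, dH_act=40 + 0.5 * d, chi_nbo=-d / 1000)
            for i, d in enumerate([-50.0, -30.0, -10.0, -20.0])
        ]
        with pytest.raises(CollinearityError):
            fit_lfer(records, descriptor="chi_nbo")

    def test_too_few_records(self):
        records = [
            ReactionRecord(id="a", dH_r=-10.0, dH_act=30.0, n3=1),
            ReactionRecord(id="b", dH_r=-20.0, dH_act=25.0, n3=2),
        ]
        with pytest.raises(ValueError, match="at least 3"):
            fit_lfer(records, descriptor="n3")

    def test_mixed_reagent_classes_need_explicit_flag(self):
        table, _ = noiseless_table()
        records = [
            ReactionRecord(
                id=r.id, dH_r=r.dH_r, dH_act=r.dH_act, n3=r.n3,
                reagent="methyl_radical" if i % 2 else "amide_anion",
            )
            for i, r in enumerate(table.records)
        ]
        with pytest.raises(ValueError, match="reagent"):
            fit_lfer(records, descriptor="n3")
        fit = fit_lfer(records, descriptor="n3", allow_mixed_reagents=True)
        assert fit.n_records == len(records)

    def test_bep_fit_has_no_beta(self):
        table, _ = noiseless_table()
        fit = fit_lfer(table.records, descriptor="none")
        assert fit.params.beta is None
        assert fit.descriptor_used == "none"

    def test_quadratic_term_recovered(self):
        rng = np.random.default_rng(7)
        dhr = rng.uniform(-60, -10, 15)
        n3 = rng.integers(0, 4, 15)
        y = 40 + 0.5 * dhr - 10 * n3 + 0.002 * dhr**2
        records = [
            ReactionRecord(id=f"q{i}", dH_r=float(d), dH_act=float(v), n3=int(k))
            for i, (d, v, k) in enumerate(zip(dhr, y, n3))
        ]
        fit = fit_lfer(records, descriptor="n3", include_quadratic=True)
        assert fit.quadratic_coef == pytest.approx(0.002, abs=1e-8)

    def test_residuals_orthogonal_to_design(self):
        table, _ = noiseless_table(n=30)
        # add noise so residuals are nonzero
        noisy = generate(GeneratorSpec(noise_sigma=3.0, seed=5, n=30))
        fit = fit_lfer(noisy.records, descriptor="n3")
        resid = fit.residuals
        dhr = np.array([r.dH_r for r in noisy.records])
        chi = np.array([r.n3 for r in noisy.records], dtype=float)
        assert abs(resid.sum()) < 1e-8
        assert abs(resid @ dhr) < 1e-6
        assert abs(resid @ chi) < 1e-8

    def test_fit_invariant_to_record_order(self):
        noisy = generate(GeneratorSpec(noise_sigma=2.0, seed=11))
        fit_a = fit_lfer(noisy.records, descriptor="n3")
        fit_b = fit_lfer(list(reversed(noisy.records)), descriptor="n3")
        assert fit_a.params.alpha == pytest.approx(fit_b.params.alpha, rel=1e-12)
        assert fit_a.params.beta == pytest.approx(fit_b.params.beta, rel=1e-12)
        assert fit_a.params.intercept == pytest.approx(fit_b.params.intercept, rel=1e-12)
        assert fit_a.r_squared == pytest.approx(fit_b.r_squared, abs=1e-12)

    def test_energy_rescaling_transforms_coefficients(self):
        """Re-unitizing energies scales intercept/beta, leaves alpha and R2."""
        noisy = generate(GeneratorSpec(noise_sigma=2.0, seed=3))
        s = 4.184  # e.g. kcal -> kJ
        scaled = [
            ReactionRecord(id=r.id, dH_r=s * r.dH_r, dH_act=s * r.dH_act, n3=r.n3)
            for r in noisy.records
        ]
        base = fit_lfer(noisy.records, descriptor="n3")
        resc = fit_lfer(scaled, descriptor="n3")
        assert resc.params.alpha == pytest.approx(base.params.alpha, rel=1e-10)
        assert resc.params.beta == pytest.approx(s * base.params.beta, rel=1e-10)
        assert resc.params.intercept == pytest.approx(s * base.params.intercept, rel=1e-10)
        assert resc.r_squared == pytest.approx(base.r_squared, abs=1e-12)
        assert resc.rmse == pytest.approx(s * base.rmse, rel=1e-10)

    def test_rmse_denominator_variants(self):
        noisy = generate(GeneratorSpec(noise_sigma=2.0, seed=9, n=12))
        fit = fit_lfer(noisy.records, descriptor="n3")
        np.testing.assert_allclose(
            fit.rmse_dof, fit.rmse * np.sqrt(12 / (12 - 3)), rtol=1e-12
        )


class TestParameterRecovery:
    def test_unbiased_over_replicates(self):
        """Coefficient estimates are unbiased; recovery error shrinks ~ sigma/sqrt(n)."""
        alphas, betas = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UnphysicalParameterWarning)
            for seed in range(200):
                table = generate(GeneratorSpec(noise_sigma=2.0, seed=seed, n=12))
                fit = fit_lfer(table.records, descriptor="n3")
                alphas.append(fit.params.alpha)
                betas.append(fit.params.beta)
        alphas, betas = np.array(alphas), np.array(betas)
        se_alpha = alphas.std(ddof=1) / np.sqrt(len(alphas))
        se_beta = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(alphas.mean() - 0.5) < 3 * se_alpha
        assert abs(betas.mean() - (-10.0)) < 3 * se_beta

    def test_recovery_error_scales_with_noise(self):
        """RMSE of recovered alpha grows roughly linearly in sigma (OLS theory)."""
        def alpha_rmse(sigma):
            errs = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UnphysicalParameterWarning)
                for seed in range(80):
                    table = generate(GeneratorSpec(noise_sigma=sigma, seed=seed, n=24))
                    errs.append(fit_lfer(table.records, "n3").params.alpha - 0.5)
            return float(np.sqrt(np.mean(np.square(errs))))

        r1, r4 = alpha_rmse(1.0), alpha_rmse(4.0)
        assert r4 / r1 == pytest.approx(4.0, rel=0.35)


class TestPredict:
    def test_empty_records_give_empty_output(self):
        table, _ = noiseless_table()
        fit = fit_lfer(table.records, descriptor="n3")
        assert predict_barriers([], fit) == []

    def test_noiseless_holdout_is_exact(self):
        table, spec = noiseless_table(n=13)
        held, train = table.records[0], table.records[1:]
        fit = fit_lfer(train, descriptor="n3")
        (_, pred), = predict_barriers([held], fit)
        assert pred == pytest.approx(held.dH_act, abs=1e-8)

    def test_zero_chi_record_gets_bep_prediction(self):
        table, _ = noiseless_table()
        fit = fit_lfer(table.records, descriptor="n3")
        probe = ReactionRecord(id="p", dH_r=-33.3, n3=0)
        (_, pred), = predict_barriers([probe], fit)
        assert pred == pytest.approx(fit.params.intercept + fit.params.alpha * -33.3)

    def test_missing_descriptor_lists_offending_ids(self):
        table, _ = noiseless_table()
        fit = fit_lfer(table.records, descriptor="n3")
        bad = [ReactionRecord(id="nope", dH_r=-20.0), table.records[0]]
        with pytest.raises(ValueError, match="nope"):
            predict_barriers(bad, fit)


class TestCompareModels:
    def test_models_coincide_when_beta_is_zero(self):
        table = generate(GeneratorSpec(alpha=0.5, beta=0.0, noise_sigma=1.0, seed=2, n=20))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UnphysicalParameterWarning)
            results = compare_models(table.records, descriptors=("none", "n3"))
        # beta carries no signal: adding it cannot help much, and the nested
        # R2 inequality still holds
        assert results["n3"].r_squared >= results["none"].r_squared - 1e-10

    def test_descriptor_model_beats_bep_when_beta_strong(self):
        table = generate(GeneratorSpec(alpha=0.5, beta=-10.0, noise_sigma=1.0, seed=4))
        results = compare_models(table.records, descriptors=("none", "n3"))
        assert results["n3"].r_squared > results["none"].r_squared
        assert results["n3"].rmse < results["none"].rmse

    def test_nested_r2_never_decreases(self):
        for seed in range(10):
            table = generate(GeneratorSpec(noise_sigma=3.0, seed=seed))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UnphysicalParameterWarning)
                results = compare_models(table.records, descriptors=("none", "n3"))
            assert results["n3"].r_squared >= results["none"].r_squared - 1e-12

    def test_summary_table_alignment(self):
        table = generate(GeneratorSpec(noise_sigma=1.0, seed=8))
        results = compare_models(table.records, descriptors=("none", "n3"))
        df = summary_table(results)
        assert list(df["descriptor"]) == ["none", "n3"]
        assert (df["n"] == len(table)).all()


class TestDecomposeVsReference:
    def test_reference_against_itself_is_zero(self):
        table, _ = noiseless_table()
        fit = fit_lfer(table.records, descriptor="n3")
        parts = decompose_vs_reference(table.records, fit, table.records[0].id)
        self_part = [p for p in parts if p.compound_id == table.records[0].id][0]
        assert self_part.strain_term == self_part.deloc_term == self_part.total == 0.0

    def test_unit_descriptor_difference(self):
        p = LFERParameters(alpha=0.5, beta=-10.0, intercept=40.0)
        records = [
            ReactionRecord(id="ref", dH_r=-30.0, dH_act=15.0, n3=1),
            ReactionRecord(id="x", dH_r=-30.0, dH_act=5.0, n3=2),
            ReactionRecord(id="y", dH_r=-40.0, dH_act=10.0, n3=1),
        ]
        fit = fit_lfer(records, descriptor="n3")
        parts = {q.compound_id: q for q in decompose_vs_reference(records, fit, "ref")}
        assert parts["x"].strain_term == pytest.approx(0.0)
        assert parts["x"].deloc_term == pytest.approx(fit.params.beta)

    def test_unknown_reference_raises(self):
        table, _ = noiseless_table()
        fit = fit_lfer(table.records, descriptor="n3")
        with pytest.raises(KeyError, match="ghost"):
            decompose_vs_reference(table.records, fit, "ghost")


def test_loo_diagnostics_small_errors_on_near_noiseless_data():
    table = generate(GeneratorSpec(noise_sigma=0.01, seed=6, n=15))
    df = loo_diagnostics(table.records, descriptor="n3")
    assert len(df) == 15
    assert df["loo_error"].abs().max() < 0.2
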