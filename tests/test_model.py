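"""GREML estimation, BLUE, CE-form GBLUP and reliabilities."""

import numpy as np
import pytest

import haploblup as hb
from haploblup.mme import mme_reliability, solve_mme
from haploblup.model import _greml


def _fit_fixed_variances(y, X, grms, model, sigmas):
    """Fit with variance components pinned at given values (no REML)."""
    return hb.fit_model(y, X, grms, model, max_iter=0, init=np.array(sigmas))


@pytest.fixture(scope="module")
def pop(small_pop):
    y = small_pop["pheno"]["trait"].to_numpy()
    X, _ = hb.build_fixed_design(small_pop["pheno"]["year_season"].to_numpy())
    return {**small_pop, "y": y, "X": X}


class TestGreml:
    def test_null_phenotype_recovers_no_heritability(self, pop500):
        rng = np.random.default_rng(123)
        y = rng.standard_normal(500)
        fit = hb.fit_model(y, np.ones((500, 1)), pop500["grms"], model=6)
        assert fit.herit["add"] <= 0.05

    def test_identity_grm_total_variance_closed_form(self):
        # with A = I the additive and residual variances are separately
        # non-identifiable but their sum is the REML total: var(y, ddof=1)
        rng = np.random.default_rng(5)
        y = rng.standard_normal(30) * 2.0 + 1.0
        fit = hb.fit_model(
            y, np.ones((30, 1)), {"add": np.eye(30)}, model=6, tol=1e-10
        )
        assert fit.varcomp.total == pytest.approx(
            np.var(y, ddof=1), rel=1e-5
        )

    def test_em_never_decreases_likelihood(self, pop):
        fit = hb.fit_model(
            pop["y"], pop["X"], pop["grms"], model=1,
            algorithm="em", max_iter=40, tol=0,
        )
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-9)

    def test_location_invariance(self, pop):
        f1 = hb.fit_model(pop["y"], pop["X"], pop["grms"], model=6)
        f2 = hb.fit_model(pop["y"] + 100.0, pop["X"], pop["grms"], model=6)
        np.testing.assert_allclose(
            f1.gblup()["total"], f2.gblup()["total"], atol=1e-6
        )
        assert f2.beta[0] - f1.beta[0] == pytest.approx(100.0, abs=1e-6)

    def test_snp_models_ignore_haplotype_grm(self, pop):
        grms = pop["grms"].by_component()
        garbage = dict(grms)
        garbage["hap"] = np.full_like(grms["hap"], np.nan)
        for mid in (5, 6):
            f1 = hb.fit_model(pop["y"], pop["X"], grms, model=mid)
            f2 = hb.fit_model(pop["y"], pop["X"], garbage, model=mid)
            assert f1.varcomp.genetic == f2.varcomp.genetic
            np.testing.assert_array_equal(
                f1.gblup()["total"], f2.gblup()["total"]
            )

    def test_heritability_sum_identity(self, pop):
        fit = hb.fit_model(pop["y"], pop["X"], pop["grms"], model=1)
        assert fit.herit.h2_total == pytest.approx(
            sum(fit.herit.by_component.values()), abs=1e-15
        )
        assert 0 <= fit.herit.h2_total <= 1

    def test_unknown_algorithm_rejected(self, pop):
        with pytest.raises(ValueError, match="algorithm"):
            _greml(
                pop["y"], pop["X"], [np.eye(100)], algorithm="newton"
            )


class TestBlue:
    def test_gls_reduces_to_ols_with_identity_v(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(40), rng.standard_normal(40)])
        y = X @ [1.0, 2.0] + rng.standard_normal(40)
        b = hb.blue_fixed_effects(y, X, np.eye(40))
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(b, ols, atol=1e-10)

    def test_balanced_two_level_contrast_is_mean_difference(self):
        labels = np.array([0] * 20 + [1] * 20)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(40) + 3.0 * labels
        X, _ = hb.build_fixed_design(labels)
        b = hb.blue_fixed_effects(y, X, np.eye(40))
        assert b[1] == pytest.approx(
            y[labels == 1].mean() - y[labels == 0].mean(), abs=1e-10
        )

    def test_simulated_fixed_effect_recovered(self, small_pop):
        cfg = hb.SimConfig(
            n_individuals=100,
            n_chromosomes=1,
            chrom_length_bp=5_000_000,
            n_snps_per_chrom=120,
            n_year_seasons=2,
            year_season_effects=(0.0, 5.0),
            seed=31,
        )
        pheno, _ = hb.simulate_phenotypes(
            small_pop["genotypes"], small_pop["blocks"], cfg
        )
        y = pheno["trait"].to_numpy()
        X, _ = hb.build_fixed_design(pheno["year_season"].to_numpy())
        fit = hb.fit_model(y, X, small_pop["grms"], model=6)
        # contrast close to the simulated +5 season effect
        assert fit.beta[1] == pytest.approx(5.0, abs=0.8)


class TestGblup:
    def test_no_residual_predicts_training_phenotypes(self, pop):
        # heritability -> 1: shrinkage vanishes, a_hat -> y - Xb on training
        fit = _fit_fixed_variances(
            pop["y"], pop["X"], pop["grms"], 6, [1.0, 1e-6]
        )
        pred = fit.gblup()["total"]
        resid = pop["y"] - fit.fitted_fixed()
        np.testing.assert_allclose(pred, resid, atol=1e-3)

    def test_zero_genetic_variance_predicts_zero(self, pop):
        fit = hb.fit_model(
            pop["y"], pop["X"], pop["grms"], 6,
            max_iter=0, init=np.array([1e-14, 1.0]), floor_frac=1e-16,
        )
        np.testing.assert_allclose(fit.gblup()["total"], 0.0, atol=1e-10)

    def test_total_is_sum_of_components(self, pop):
        fit = hb.fit_model(pop["y"], pop["X"], pop["grms"], model=1)
        parts = fit.gblup()
        np.testing.assert_allclose(
            parts["total"],
            parts["add"] + parts["dom"] + parts["hap"],
            atol=1e-12,
        )

    def test_ce_equals_mme_on_small_instance(self):
        """8 training individuals: CE predictions, effects, beta and
        reliabilities all match the explicit Henderson system to 1e-8."""
        cfg = hb.SimConfig(
            n_individuals=12,
            n_chromosomes=1,
            chrom_length_bp=500_000,
            n_snps_per_chrom=20,
            n_founders=10,
            seed=3,
        )
        g = hb.simulate_genotypes(cfg)
        blocks = hb.build_fixed_blocks(g, 100)
        dm = hb.build_design_matrices(g, blocks)
        grms = hb.build_grms(dm)
        pheno, _ = hb.simulate_phenotypes(g, blocks, cfg)
        y = pheno["trait"].to_numpy()
        X, _ = hb.build_fixed_design(pheno["year_season"].to_numpy())
        tr = np.arange(8)
        fit = hb.fit_model(y, X, grms, model=1, train_idx=tr)
        sig = dict(fit.varcomp.genetic)
        t_all = {c: dm.T(c) for c in fit.spec.components}
        t_tr = {c: t_all[c][tr] for c in fit.spec.components}
        sol = solve_mme(y[tr], X[tr], t_tr, sig, fit.varcomp.residual)
        pred = fit.gblup()
        for c in fit.spec.components:
            np.testing.assert_allclose(
                pred[c], t_all[c] @ sol.effects[c], atol=1e-8
            )
        np.testing.assert_allclose(fit.beta, sol.beta, atol=1e-8)
        np.testing.assert_allclose(
            fit.reliability(), mme_reliability(sol, t_all, sig), atol=1e-8
        )


class TestReliability:
    def test_in_unit_interval(self, pop):
        fit = hb.fit_model(pop["y"], pop["X"], pop["grms"], model=1)
        r = fit.reliability()
        assert np.all(r >= 0) and np.all(r <= 1)

    def test_near_one_when_residual_vanishes(self, pop):
        fit = _fit_fixed_variances(
            pop["y"], np.ones((100, 1)), pop["grms"], 6, [1.0, 1e-10]
        )
        r = fit.reliability()
        assert r.min() > 0.95

    def test_zero_for_unrelated_validation_individual(self):
        rng = np.random.default_rng(3)
        n = 12
        a = np.eye(n)  # everyone unrelated
        y = rng.standard_normal(n)
        fit = _fit_fixed_variances(
            y, np.ones((n, 1)), {"add": a}, 6, [0.5, 0.5]
        )
        fit2 = hb.fit_model(
            y, np.ones((n, 1)), {"add": a}, 6,
            train_idx=np.arange(8), max_iter=0,
            init=np.array([0.5, 0.5]),
        )
        r = fit2.reliability()
        np.testing.assert_allclose(r[8:], 0.0, atol=1e-10)
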