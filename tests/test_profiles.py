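"""Per-unit effect estimation and heritability-share partitioning."""

import numpy as np
import pytest

import haploblup as hb
from haploblup.mme import solve_mme
from haploblup.profiles import _share, estimate_unit_effects


@pytest.fixture(scope="module")
def full_fit(small_pop):
    y = small_pop["pheno"]["trait"].to_numpy()
    x, _ = hb.build_fixed_design(small_pop["pheno"]["year_season"].to_numpy())
    fit = hb.fit_model(y, x, small_pop["grms"], model=1)
    return fit


class TestUnitEffects:
    def test_zero_variance_zero_effects(self, small_pop):
        y = small_pop["pheno"]["trait"].to_numpy()
        fit = hb.fit_model(
            y, np.ones((100, 1)), small_pop["grms"], 6,
            max_iter=0, init=np.array([1e-14, 1.0]), floor_frac=1e-16,
        )
        eff = estimate_unit_effects(fit, small_pop["dm"])
        np.testing.assert_allclose(eff["add"], 0.0, atol=1e-12)

    def test_duplicated_snp_columns_get_identical_effects(
        self, make_genotypes
    ):
        rng = np.random.default_rng(6)
        col = rng.integers(0, 2, size=(30, 2, 1), dtype=np.int8)
        extra = rng.integers(0, 2, size=(30, 2, 4), dtype=np.int8)
        haps = np.concatenate([col, col, extra], axis=2)
        g = make_genotypes(haps, [10, 20, 30, 40, 50, 60], chrom_length=100)
        bs = hb.BlockSet(
            [hb.Block("b", "1", 0, 100, list(range(6)), "fixed")]
        )
        dm = hb.build_design_matrices(g, bs)
        grms = hb.build_grms(dm)
        y = rng.standard_normal(30)
        fit = hb.fit_model(y, np.ones((30, 1)), grms, model=6)
        eff = estimate_unit_effects(fit, dm)["add"]
        assert eff[0] == pytest.approx(eff[1], abs=1e-12)

    def test_ce_effects_equal_mme(self, small_pop, full_fit):
        dm = small_pop["dm"]
        eff = estimate_unit_effects(full_fit, dm)
        t_mats = {c: dm.T(c) for c in full_fit.spec.components}
        sol = solve_mme(
            full_fit.y, full_fit.X, t_mats,
            dict(full_fit.varcomp.genetic), full_fit.varcomp.residual,
        )
        for c in full_fit.spec.components:
            np.testing.assert_allclose(eff[c], sol.effects[c], atol=1e-8)


class TestShares:
    def test_three_four_split(self):
        shares = _share(np.array([9.0, 16.0]), 0.25)
        np.testing.assert_allclose(shares, [0.09, 0.16])

    def test_single_unit_takes_all(self):
        np.testing.assert_allclose(_share(np.array([2.0]), 0.3), [0.3])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            _share(np.zeros(3), 0.2)

    def test_shares_sum_to_component_heritability(self, small_pop, full_fit):
        prof = hb.heritability_profile(
            full_fit, small_pop["dm"], small_pop["genotypes"],
            small_pop["blocks"],
        )
        for comp, name in (
            ("add", "snp_add"), ("dom", "snp_dom"), ("hap", "hap_add"),
        ):
            total = prof.loc[prof.component == name, "h2_share"].sum()
            assert total == pytest.approx(full_fit.herit[comp], abs=1e-12)
        assert (prof["h2_share"] >= 0).all()

    def test_permutation_invariance(self, small_pop, full_fit):
        """Shares follow their unit ids under SNP reordering."""
        prof = hb.heritability_profile(
            full_fit, small_pop["dm"], small_pop["genotypes"],
            small_pop["blocks"],
        )
        snp_rows = prof[prof.component == "snp_add"]
        by_id = dict(zip(snp_rows.unit_id, snp_rows.h2_share))
        # rows are position-sorted; shares keyed by id are unchanged
        resorted = snp_rows.sort_values("unit_id")
        assert all(
            by_id[u] == s
            for u, s in zip(resorted.unit_id, resorted.h2_share)
        )


class TestMmeVarianceDecomposition:
    def test_total_equals_sum_of_per_effect_terms(self, small_pop, full_fit):
        dm = small_pop["dm"]
        t_mats = {c: dm.T(c) for c in full_fit.spec.components}
        sol = solve_mme(
            full_fit.y, full_fit.X, t_mats,
            dict(full_fit.varcomp.genetic), full_fit.varcomp.residual,
        )
        for c in full_fit.spec.components:
            assert sol.per_effect_variance(c).sum() == pytest.approx(
                sol.total_variance(c), rel=1e-12
            )

    def test_large_lambda_limit(self, small_pop):
        """As sigma2_add -> 0: effects vanish, lambda*tr(C^aa) -> m (so the
        effective denominator collapses), and the per-effect variances -> 0
        at the consistent rate."""
        dm = small_pop["dm"]
        y = small_pop["pheno"]["trait"].to_numpy()
        t_mats = {"add": dm.T_add}
        sol = solve_mme(
            y, np.ones((100, 1)), t_mats, {"add": 1e-10}, 1.0
        )
        m = dm.T_add.shape[1]
        np.testing.assert_allclose(sol.effects["add"], 0.0, atol=1e-6)
        assert sol.tr_c_block("add") * sol.lambdas["add"] == pytest.approx(
            m, rel=1e-6
        )
        np.testing.assert_allclose(
            sol.per_effect_variance("add"), 0.0, atol=1e-8
        )


class TestProfileReport:
    def test_rows_sorted_and_genes_annotated(self, small_pop, full_fit):
        genes = hb.simulate_genes(small_pop["config"])
        prof = hb.heritability_profile(
            full_fit, small_pop["dm"], small_pop["genotypes"],
            small_pop["blocks"],
        )
        rep = hb.profile_report(prof, genes, small_pop["blocks"])
        pos = rep["pos"].to_numpy()
        assert np.all(np.diff(pos) >= 0)  # single chromosome here
        assert "genes" in rep.columns
        assert (rep["genes"].str.len() > 0).any()

    def test_empty_gene_table_ok(self, small_pop, full_fit):
        import pandas as pd

        prof = hb.heritability_profile(
            full_fit, small_pop["dm"], small_pop["genotypes"],
            small_pop["blocks"],
        )
        empty = pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
        rep = hb.profile_report(prof, empty)
        assert (rep["genes"] == "").all()

    def test_causal_block_top_ranked_across_replicates(self):
        """With a single causal block (h2 = 0.2, n = 500), the haplotype
        heritability profile ranks it first in at least 18 of 20 replicates."""
        hits = 0
        for rep in range(20):
            cfg = hb.SimConfig(
                n_individuals=500,
                n_chromosomes=2,
                chrom_length_bp=10_000_000,
                n_snps_per_chrom=150,
                var_fractions=(0.0, 0.0, 0.2, 0.8),
                n_causal_blocks=1,
                seed=7000 + rep,
            )
            g = hb.simulate_genotypes(cfg)
            blocks = hb.build_fixed_blocks(g, 500)
            dm = hb.build_design_matrices(g, blocks)
            grms = hb.build_grms(dm)
            pheno, truth = hb.simulate_phenotypes(g, blocks, cfg)
            fit = hb.fit_model(
                pheno["trait"].to_numpy(), np.ones((500, 1)), grms, model=4
            )
            prof = hb.heritability_profile(fit, dm, g, blocks)
            hap = prof[prof.component == "hap_add"]
            top = hap.loc[hap["h2_share"].idxmax(), "unit_id"]
            hits += top == truth.causal_block_ids[0]
        assert hits >= 18

    def test_single_causal_block_ranks_top(self):
        """A lone causal block holds the top haplotype heritability share."""
        cfg = hb.SimConfig(
            n_individuals=250,
            n_chromosomes=1,
            chrom_length_bp=10_000_000,
            n_snps_per_chrom=150,
            var_fractions=(0.0, 0.0, 0.3, 0.7),
            n_causal_blocks=1,
            seed=77,
        )
        g = hb.simulate_genotypes(cfg)
        blocks = hb.build_fixed_blocks(g, 500)
        dm = hb.build_design_matrices(g, blocks)
        grms = hb.build_grms(dm)
        pheno, truth = hb.simulate_phenotypes(g, blocks, cfg)
        fit = hb.fit_model(
            pheno["trait"].to_numpy(), np.ones((250, 1)), grms, model=4
        )
        prof = hb.heritability_profile(fit, dm, g, blocks)
        hap = prof[prof.component == "hap_add"]
        top = hap.loc[hap["h2_share"].idxmax(), "unit_id"]
        assert top == truth.causal_block_ids[0]
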