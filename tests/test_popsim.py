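"""Generative-model tests: panel layout, LD, Mendelian transmission,
assortative mating, and the phenotype standardization formula."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import pgsdesign as pg
from pgsdesign.popsim import StratumSpec


class TestSnpPanel:
    @pytest.mark.parametrize(
        "m,block_size,expected_sizes",
        [(10, 5, [5, 5]), (7, 3, [3, 3, 1]), (4, 10, [4])],
    )
    def test_block_layout(self, m, block_size, expected_sizes):
        panel = pg.make_snp_panel(m, block_size=block_size, seed=0)
        sizes = panel.table.groupby("block_id").size().tolist()
        assert sizes == expected_sizes

    def test_degenerate_maf_interval(self):
        panel = pg.make_snp_panel(12, maf_low=0.3, maf_high=0.3, seed=0)
        assert np.allclose(panel.maf, 0.3)

    def test_positions_strictly_increasing_and_blocks_separated(self):
        panel = pg.make_snp_panel(30, block_size=10, seed=1)
        pos = panel.table["pos"].to_numpy()
        assert np.all(np.diff(pos) > 0)
        # default gap puts distinct blocks beyond a 1 Mb clumping window
        b = panel.block_ids
        gaps = pos[1:][b[1:] != b[:-1]] - pos[:-1][b[1:] != b[:-1]]
        assert np.all(gaps > 1_000_000)

    @pytest.mark.parametrize("kwargs", [{"m": 0}, {"m": 5, "block_size": 0},
                                        {"m": 5, "maf_low": 0.0}, {"m": 5, "maf_high": 0.6}])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            pg.make_snp_panel(**{"block_size": 5, **kwargs})


class TestSimulateUnrelated:
    def test_seed_determinism(self, small_panel):
        a = pg.simulate_unrelated(small_panel, 50, seed=5)
        b = pg.simulate_unrelated(small_panel, 50, seed=5)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_allele_frequencies_match_panel(self, small_panel):
        geno = pg.simulate_unrelated(small_panel, 4000, seed=7)
        freq = geno.counts.mean(axis=0) / 2.0
        tol = 4.0 * np.sqrt(small_panel.maf * (1 - small_panel.maf) / 8000)
        assert np.all(np.abs(freq - small_panel.maf) < tol)

    def test_unlinked_panel_has_null_level_ld(self):
        panel = pg.make_snp_panel(30, block_size=5, within_block_r=0.0, seed=3)
        geno = pg.simulate_unrelated(panel, 1000, seed=4)
        r = np.corrcoef(geno.counts.T)
        off = r[np.triu_indices_from(r, k=1)] ** 2
        # sample r^2 under independence has mean ~ 1/n
        assert off.mean() < 3.0 / 1000

    def test_within_block_exceeds_cross_block_correlation(self):
        panel = pg.make_snp_panel(20, block_size=10, within_block_r=0.9, seed=5)
        geno = pg.simulate_unrelated(panel, 5000, seed=6)
        c = geno.counts
        adjacent = np.corrcoef(c[:, 0], c[:, 1])[0, 1]
        cross = abs(np.corrcoef(c[:, 0], c[:, 10])[0, 1])
        assert adjacent > 0.5 > cross


class TestEffectSizes:
    def test_beta_variance_matches_generative_model(self):
        # 10K causal SNPs at h2=0.5 -> per-SNP effect variance 5e-5
        panel = pg.make_snp_panel(10_000, block_size=1, within_block_r=0.0, seed=8)
        eff = pg.draw_effect_sizes(panel, 10_000, h2=0.5, seed=9)
        assert eff.beta_direct.var() == pytest.approx(5e-5, rel=0.05)

    def test_zero_heritability_gives_zero_effects(self, small_panel):
        eff = pg.draw_effect_sizes(small_panel, 10, h2=0.0, seed=1)
        assert np.all(eff.beta_direct == 0)

    def test_indirect_correlation_is_controlled(self):
        panel = pg.make_snp_panel(500, block_size=1, within_block_r=0.0, seed=2)
        eff = pg.draw_effect_sizes(panel, 500, h2=0.5, rho_di=-0.9, indirect_scale=1.0, seed=3)
        r = np.corrcoef(eff.beta_direct, eff.beta_indirect)[0, 1]
        assert abs(r - (-0.9)) < 0.05
        assert eff.beta_indirect.std() == pytest.approx(eff.beta_direct.std(), rel=0.05)

    def test_invalid_parameters(self, small_panel):
        with pytest.raises(ValueError):
            pg.draw_effect_sizes(small_panel, 10, h2=1.5)
        with pytest.raises(ValueError):
            pg.draw_effect_sizes(small_panel, 10, h2=0.5, rho_di=1.5)


class TestGeneticScore:
    def test_single_row_arithmetic(self):
        panel = pg.make_snp_panel(3, block_size=1, maf_low=0.4, maf_high=0.4, seed=0)
        geno = pg.GenotypeMatrix(panel, np.array([[0, 1, 2]], dtype=np.int8))
        eff = pg.EffectModel(panel.snp_ids, [0.5, -0.2, 0.1], np.zeros(3), h2=0.5)
        assert pg.genetic_score(geno, eff)[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self, small_panel):
        rng = np.random.default_rng(0)
        geno = pg.simulate_unrelated(small_panel, 20, seed=1)
        causal = small_panel.snp_ids[rng.choice(small_panel.m, 5, replace=False)]
        beta = rng.normal(size=5)
        eff = pg.EffectModel(causal, beta, np.zeros(5), h2=0.5)
        got = pg.genetic_score(geno, eff)
        idx = small_panel.index_of(causal)
        expected = [sum(geno.counts[i, idx[k]] * beta[k] for k in range(5)) for i in range(20)]
        assert np.allclose(got, expected, atol=1e-12)

    def test_missing_causal_snp_raises(self, small_panel, small_geno):
        eff = pg.EffectModel(np.array(["nope"]), [1.0], [0.0], h2=0.5)
        with pytest.raises(KeyError):
            pg.genetic_score(small_geno, eff)


class TestMating:
    def test_random_mating_has_null_spousal_correlation(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=4000)
        couples = pg.mate_parents(y, 0.0, seed=1)
        r = np.corrcoef(y[couples[:, 0]], y[couples[:, 1]])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(2000)

    def test_target_spousal_correlation(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=10_000)
        couples = pg.mate_parents(y, 0.3, seed=3)
        r = np.corrcoef(y[couples[:, 0]], y[couples[:, 1]])[0, 1]
        assert r == pytest.approx(0.3, abs=0.05)

    def test_near_deterministic_rank_matching_limit(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=4000)
        couples = pg.mate_parents(y, 0.99, seed=5)
        r = np.corrcoef(y[couples[:, 0]], y[couples[:, 1]])[0, 1]
        assert r >= 0.95

    def test_each_parent_used_once(self):
        y = np.random.default_rng(6).normal(size=500)
        couples = pg.mate_parents(y, 0.5, seed=7)
        used = np.concatenate([couples[:, 0], couples[:, 1]])
        assert len(np.unique(used)) == 500


class TestOffspring:
    def _one_snp_cohort(self, parent_haps, n_families, seed=0):
        panel = pg.make_snp_panel(1, block_size=1, maf_low=0.5, maf_high=0.5, seed=0)
        haps = np.tile(parent_haps, (n_families, 1)).astype(np.int8)
        counts = haps[0::2] + haps[1::2]
        parents = pg.GenotypeMatrix(panel, counts, haps)
        n = counts.shape[0]
        couples = np.column_stack([np.arange(n // 2), n // 2 + np.arange(n // 2)])
        return pg.simulate_offspring(couples, parents, seed=seed)

    def test_monomorphic_transmission(self):
        coh0 = self._one_snp_cohort(np.array([[0], [0]]), 50)
        assert np.all(coh0.offspring.counts == 0)
        coh2 = self._one_snp_cohort(np.array([[1], [1]]), 50)
        assert np.all(coh2.offspring.counts == 2)

    def test_het_cross_segregates_1_2_1(self):
        # both parents heterozygous: offspring counts 0/1/2 with probs 1/4,1/2,1/4
        coh = self._one_snp_cohort(np.array([[0], [1]]), 5000, seed=9)
        counts = np.bincount(coh.offspring.counts.ravel(), minlength=3)
        chi2, p = sps.chisquare(counts, f_exp=len(coh.offspring.counts.ravel()) * np.array([0.25, 0.5, 0.25]))
        assert p > 0.001

    def test_mendelian_consistency_holds_and_detects_violation(self, small_cohort):
        cohort, _ = small_cohort
        assert pg.check_mendelian(cohort)
        tampered = cohort.subset_families(np.arange(cohort.n_families))
        bad = tampered.offspring.counts.copy()
        bad[0, 0] = 2 - bad[0, 0] if bad[0, 0] != 1 else 2
        # force an impossible count where both parents are homozygous ref
        gm, gf = tampered.mothers.counts[0, 0], tampered.fathers.counts[0, 0]
        bad[0, 0] = 0 if (gm == 2 and gf == 2) else 2 if (gm == 0 or gf == 0) else bad[0, 0]
        if bad[0, 0] != tampered.offspring.counts[0, 0]:
            tampered.offspring.counts = bad
            assert not pg.check_mendelian(tampered)

    def test_sibling_genotype_correlation_near_half(self, small_panel, small_effects):
        cohort, _ = pg.simulate_two_generation_cohort(small_panel, small_effects, 5000, seed=31)
        c = cohort.offspring.counts
        idx = small_panel.index_of(small_effects.causal_ids)
        rs = [np.corrcoef(c[0::2, j], c[1::2, j])[0, 1] for j in idx]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.03)

    def test_requires_haplotypes(self, small_panel):
        geno = pg.simulate_unrelated(small_panel, 10, seed=1, keep_haplotypes=False)
        with pytest.raises(ValueError):
            pg.simulate_offspring(np.array([[0, 5]]), geno)


class TestPhenotype:
    def test_standardization_formula_moments(self):
        panel = pg.make_snp_panel(400, block_size=1, within_block_r=0.0, seed=41)
        eff = pg.draw_effect_sizes(panel, 400, h2=0.5, seed=42)
        geno = pg.simulate_unrelated(panel, 20_000, seed=43, keep_haplotypes=False)
        pheno = pg.assemble_phenotype(geno, eff, seed=44)
        assert pheno["y"].var() == pytest.approx(1.0, abs=0.05)
        assert np.corrcoef(pheno["y"], pheno["g"])[0, 1] ** 2 == pytest.approx(0.5, abs=0.03)
        assert abs(pheno["y"].mean()) < 0.05

    def test_pure_genetic_trait_equals_standardized_score(self, small_panel, small_effects, small_geno):
        eff = pg.EffectModel(
            small_effects.causal_ids, small_effects.beta_direct,
            small_effects.beta_indirect, h2=1.0,
        )
        pheno = pg.assemble_phenotype(small_geno, eff, seed=1)
        g = pheno["g"].to_numpy()
        assert np.allclose(pheno["y"], (g - g.mean()) / g.std(), atol=1e-12)

    def test_indirect_effects_require_parents(self, small_geno, small_effects):
        with pytest.raises(ValueError):
            pg.assemble_phenotype(small_geno, small_effects, seed=1, indirect_weight=0.3)

    def test_indirect_component_raises_midparent_slope(self):
        panel = pg.make_snp_panel(300, block_size=5, seed=51)
        eff = pg.draw_effect_sizes(panel, 100, h2=0.4, rho_di=1.0, indirect_scale=1.0, seed=52)
        slopes = {}
        for eta in (0.0, 0.5):
            cohort, pheno = pg.simulate_two_generation_cohort(
                panel, eff, 4000, seed=53, indirect_weight=eta
            )
            midparent = np.repeat(
                (cohort.parents["mother_g"] + cohort.parents["father_g"]).to_numpy() / 2.0, 2
            )
            slopes[eta] = np.polyfit(midparent, pheno["y"].to_numpy(), 1)[0]
        assert slopes[0.5] > slopes[0.0]

    def test_stratum_multipliers_scale_variance(self):
        panel = pg.make_snp_panel(200, block_size=1, within_block_r=0.0, seed=61)
        eff = pg.draw_effect_sizes(panel, 200, h2=0.0, seed=62)
        eff.strata = [StratumSpec("A", env_scale=1.0), StratumSpec("B", env_scale=2.0)]
        geno = pg.simulate_unrelated(panel, 20_000, seed=63, keep_haplotypes=False)
        pheno = pg.assemble_phenotype(geno, eff, seed=64)
        va = pheno.loc[pheno.stratum == "A", "y"].var()
        vb = pheno.loc[pheno.stratum == "B", "y"].var()
        assert vb / va == pytest.approx(4.0, rel=0.1)

    def test_collider_stratification_correlates_with_phenotype(self):
        panel = pg.make_snp_panel(100, block_size=1, within_block_r=0.0, seed=71)
        eff = pg.draw_effect_sizes(panel, 100, h2=0.5, seed=72)
        eff.strata = [StratumSpec("low"), StratumSpec("high")]
        geno = pg.simulate_unrelated(panel, 5000, seed=73, keep_haplotypes=False)
        pheno = pg.assemble_phenotype(
            geno, eff, seed=74, stratum_assignment="collider", collider_r=0.6
        )
        means = pheno.groupby("stratum")["y"].mean()
        assert means["high"] > means["low"] + 0.3

    def test_two_generation_seed_reproducibility(self, small_panel, small_effects):
        a = pg.simulate_two_generation_cohort(small_panel, small_effects, 100, seed=81)
        b = pg.simulate_two_generation_cohort(small_panel, small_effects, 100, seed=81)
        assert np.array_equal(a[0].offspring.counts, b[0].offspring.counts)
        pd.testing.assert_frame_equal(a[1], b[1])


class TestBinarize:
    def test_threshold_semantics(self):
        assert pg.binarize_trait(np.array([1.0, 2.0, 3.0]), threshold=2.0).tolist() == [0, 0, 1]
        assert pg.binarize_trait(np.array([1.0, 2.0]), threshold=-np.inf).tolist() == [1, 1]

    def test_quantile_prevalence(self):
        y = np.random.default_rng(5).normal(size=10_000)
        b = pg.binarize_trait(y, quantile=0.8)
        assert b.mean() == pytest.approx(0.2, abs=2.0 / np.sqrt(10_000))

    def test_invalid_quantile(self):
        with pytest.raises(ValueError):
            pg.binarize_trait(np.array([1.0]), quantile=1.5)


def test_trait_simulation_grid_enumerates_full_design():
    grid = pg.trait_simulation_grid()
    assert len(grid) == 12
    assert {g["h2"] for g in grid} == {0.1, 0.5}
    assert {g["m_causal"] for g in grid} == {10_000, 100_000}
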