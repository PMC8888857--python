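"""SNP-to-gene mapping, pathway scores, FDR and the competitive
permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import stepup_bh
from pathprs import assoc, pathway as pw, pipeline
from pathprs.containers import GenotypeData, HarmonizedPanel
from pathprs.pathway import (PermutationBackground, competitive_p, concordance,
                             fdr_adjust, geneset_snps, map_snps_to_genes,
                             pathway_score, replication_filter,
                             self_contained_test)


class TestMapping:
    variants = pd.DataFrame({
        "SNP": ["a", "b", "c", "d"],
        "CHR": ["1", "1", "1", "1"],
        "BP": [101, 150, 200, 300],
    })

    def test_half_open_interval_convention(self):
        # BED [100, 200): 1-based positions 101..200 inside
        bed = pd.DataFrame([{"CHR": "1", "START": 100, "END": 200, "GENE": "g1"}])
        mapping = map_snps_to_genes(self.variants, bed)
        assert set(mapping) == {"a", "b", "c"}  # post at boundary start included
        assert "d" not in mapping  # 300 > END

    def test_position_just_past_end_excluded(self):
        bed = pd.DataFrame([{"CHR": "1", "START": 100, "END": 199, "GENE": "g1"}])
        mapping = map_snps_to_genes(self.variants, bed)
        assert "c" not in mapping  # 200 is the first position past [100,199)

    def test_overlapping_genes_map_to_all(self):
        bed = pd.DataFrame([
            {"CHR": "1", "START": 100, "END": 250, "GENE": "g1"},
            {"CHR": "1", "START": 140, "END": 210, "GENE": "g2"},
        ])
        mapping = map_snps_to_genes(self.variants, bed)
        assert sorted(mapping["b"]) == ["g1", "g2"]
        assert geneset_snps(["g2"], mapping) == ["b", "c"]

    def test_no_overlap_is_an_error(self):
        bed = pd.DataFrame([{"CHR": "9", "START": 0, "END": 50, "GENE": "g"}])
        with pytest.raises(ValueError):
            map_snps_to_genes(self.variants, bed)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_traced_stepup(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert (fdr_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            np.testing.assert_allclose(fdr_adjust(p), stepup_bh(p), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(1e-6, 1, 50)
        assert (fdr_adjust(p) >= p - 1e-15).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([])


def tiny_background(n=160, n_bg=5, seed=30):
    """A fully enumerable permutation background (5 variants)."""
    rng = np.random.default_rng(seed)
    D = rng.integers(0, 3, size=(n, n_bg)).astype(float)
    betas = rng.normal(0, 0.5, n_bg)
    logit = 0.8 * (D[:, 0] * betas[0]) - 0.2
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    cohort = pd.DataFrame({"IID": [f"s{i}" for i in range(n)], "STATUS": y,
                           "SEX": rng.integers(0, 2, n),
                           "BMI": rng.normal(25, 3, n)})
    X_cov = assoc.build_design(cohort)
    beta_cov, _, _, conv = assoc.newton_logit(y, X_cov)
    assert conv
    return PermutationBackground(
        snp_ids=np.array([f"v{j}" for j in range(n_bg)]),
        dosages_eff=D, betas=betas, y=y, X_cov=X_cov, start_cov=beta_cov)


class TestCompetitiveP:
    def test_formula_floor_when_observed_is_smallest(self):
        bg = tiny_background()
        p = competitive_p(0.0, 2, bg, n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_observed_one_gives_one(self):
        bg = tiny_background()
        assert competitive_p(1.0, 2, bg, n_perm=99, seed=1) == 1.0

    def test_converges_to_exhaustive_enumeration(self):
        bg = tiny_background()
        observed = 0.2
        # oracle: enumerate all C(5,2)=10 subsets exhaustively
        subset_ps = []
        for idx in itertools.combinations(range(bg.size), 2):
            subset_ps.append(bg.prs_p(bg.score_subset(list(idx))))
        exhaustive = np.mean([p <= observed for p in subset_ps])
        n_perm = 4000
        est = competitive_p(observed, 2, bg, n_perm=n_perm, seed=2)
        mc_se = np.sqrt(exhaustive * (1 - exhaustive) / n_perm)
        assert abs(est - exhaustive) < max(4 * mc_se, 2 / n_perm)

    def test_seeded_determinism(self):
        bg = tiny_background()
        a = competitive_p(0.3, 2, bg, n_perm=200, seed=7)
        b = competitive_p(0.3, 2, bg, n_perm=200, seed=7)
        assert a == b

    def test_k_larger_than_background_rejected(self):
        bg = tiny_background()
        with pytest.raises(ValueError):
            competitive_p(0.5, 6, bg, n_perm=10, seed=0)

    def test_zero_k_rejected(self):
        bg = tiny_background()
        with pytest.raises(ValueError):
            competitive_p(0.5, 0, bg, n_perm=10, seed=0)


class TestSelfContained:
    def test_matches_statsmodels_wald(self, small_study):
        res = pipeline.genomewide_analysis(small_study.sumstats,
                                           small_study.genotypes_target,
                                           small_study.cohort_target)
        prs = res["prs_best"]
        z, p = self_contained_test(prs, small_study.cohort_target, res["pcs"])
        a = assoc.prs_association(prs, small_study.cohort_target, res["pcs"])
        assert z == pytest.approx(a.beta_prs / a.se, abs=1e-5)
        assert p == pytest.approx(a.p_value, rel=1e-4)

    def test_permuted_phenotype_z_standard_normal(self, small_study):
        rng = np.random.default_rng(31)
        res = pipeline.genomewide_analysis(small_study.sumstats,
                                           small_study.genotypes_target,
                                           small_study.cohort_target)
        prs = res["prs_best"]
        cohort = small_study.cohort_target
        zs = []
        for _ in range(150):
            shuffled = cohort.assign(STATUS=rng.permutation(cohort["STATUS"].to_numpy()))
            z, _ = self_contained_test(prs, shuffled, res["pcs"])
            zs.append(z)
        assert stats.kstest(zs, "norm").pvalue > 0.01


class TestPathwayScore:
    def block_separated(self):
        """Two variant groups >window apart with independent genotypes."""
        rng = np.random.default_rng(32)
        n = 120
        D = rng.integers(0, 3, size=(n, 8)).astype(float)
        pos = [1000, 2000, 3000, 4000, 2_001_000, 2_002_000, 2_003_000, 2_004_000]
        variants = pd.DataFrame({
            "SNP": [f"v{j}" for j in range(8)], "CHR": "1", "BP": pos,
            "REF": "A", "ALT": "G",
        })
        panel = HarmonizedPanel(variants=variants.assign(
            BETA=rng.normal(0, 0.2, 8), P=rng.uniform(0.001, 1, 8), FLIP=False))
        geno = GenotypeData(dosages=D, variants=variants,
                            samples=[f"s{i}" for i in range(n)])
        return panel, geno

    def test_additive_over_ld_separated_sets(self):
        panel, geno = self.block_separated()
        set_a = [f"v{j}" for j in range(4)]
        set_b = [f"v{j}" for j in range(4, 8)]
        sa, _ = pathway_score(set_a, panel, geno)
        sb, _ = pathway_score(set_b, panel, geno)
        sab, _ = pathway_score(set_a + set_b, panel, geno)
        np.testing.assert_allclose(sab, sa + sb, atol=1e-9)

    def test_full_geneset_equals_genic_full_model(self):
        panel, geno = self.block_separated()
        all_ids = list(panel.variants["SNP"])
        s_all, cres = pathway_score(all_ids, panel, geno)
        from pathprs.clumpscore import clump, score
        direct = score(geno, clump(panel, geno), thresholds=(1.0,)).scores[1.0]
        np.testing.assert_allclose(s_all, direct, atol=1e-9)

    def test_empty_set_rejected(self):
        panel, geno = self.block_separated()
        with pytest.raises(ValueError):
            pathway_score(["nope"], panel, geno)


class TestConcordance:
    def test_identical_z_gives_r_one(self):
        z = np.array([0.5, 1.2, -0.3, 2.2, 0.1])
        assert concordance(z, z).pearson_r == pytest.approx(1.0)

    def test_anticorrelated_gives_minus_one(self):
        z = np.array([0.5, 1.2, -0.3, 2.2, 0.1])
        res = concordance(z, -z)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_independent_null_near_zero(self):
        rng = np.random.default_rng(33)
        rs = [concordance(rng.normal(size=100), rng.normal(size=100)).pearson_r
              for _ in range(50)]
        assert abs(np.mean(rs)) < 0.05
        assert np.std(rs) == pytest.approx(0.1, abs=0.05)  # ~1/sqrt(100)

    def test_too_few_pathways_rejected(self):
        with pytest.raises(ValueError):
            concordance([1.0, 2.0], [1.0, 2.0])


class TestReplication:
    def frame(self, names, qs, zs):
        return pd.DataFrame({"name": names, "q_fdr": qs, "z": zs})

    def test_requires_significance_in_both_and_same_direction(self):
        tgt = self.frame(["a", "b", "c", "d"], [0.01, 0.01, 0.2, 0.01],
                         [2.0, 2.0, 2.0, 2.0])
        val = self.frame(["a", "b", "c", "d"], [0.01, 0.2, 0.01, 0.01],
                         [2.0, 2.0, 2.0, -2.0])
        out = replication_filter(tgt, val)
        assert list(out["name"]) == ["a"]

    def test_empty_target_significant_set(self):
        tgt = self.frame(["a"], [0.9], [1.0])
        val = self.frame(["a"], [0.01], [1.0])
        assert len(replication_filter(tgt, val)) == 0


class TestEnrichmentDetection:
    def test_enriched_pathway_has_smallest_competitive_p(self, small_study):
        res = pipeline.genomewide_analysis(small_study.sumstats,
                                           small_study.genotypes_target,
                                           small_study.cohort_target)
        table = pw.run_pathway_analysis(
            small_study.gene_sets, small_study.gene_bed, res["panel"],
            res["geno_qc"], small_study.cohort_target, res["pcs"],
            n_perm=200, seed=40)
        best = table.loc[table["p_comp"].idxmin(), "name"]
        assert best == small_study.enriched_pathway
        assert table["p_comp"].min() <= 0.05

    def test_scattered_signal_gives_uniform_competitive_p(self):
        """With causal variants scattered uniformly (no set enrichment) the
        competitive p is roughly uniform even though self-contained p is
        systematically small — the defining contrast of the competitive null."""
        data = pipeline.simulate_dataset(
            77, n_individuals=600, n_variants=900, n_blocks=30, n_causal=300,
            heritability=0.5, n_genes=60, n_pathways=24,
            pathway_size_range=(5, 12), enriched_frac=0.0, two_cohorts=False)
        res = pipeline.genomewide_analysis(data.sumstats, data.genotypes_target,
                                           data.cohort_target)
        table = pw.run_pathway_analysis(
            data.gene_sets, data.gene_bed, res["panel"], res["geno_qc"],
            data.cohort_target, res["pcs"], n_perm=200, seed=41)
        # self-contained p: polygenic signal everywhere
        assert (table["p_self"] < 0.05).mean() > 0.5
        # competitive p: no pathway stands out against the background
        assert table["p_comp"].mean() > 0.25
        assert (table["p_comp"] < 0.05).mean() <= 0.15

    def test_pathway_table_invariants(self, small_study):
        res = pipeline.genomewide_analysis(small_study.sumstats,
                                           small_study.genotypes_target,
                                           small_study.cohort_target)
        table = pw.run_pathway_analysis(
            small_study.gene_sets, small_study.gene_bed, res["panel"],
            res["geno_qc"], small_study.cohort_target, res["pcs"],
            n_perm=50, seed=42)
        assert (table["q_fdr"] >= table["p_self"] - 1e-15).all()
        assert (table["p_comp"] >= 1 / 51).all()
        assert (table["p_comp"] <= 1.0).all()
        assert (table["n_snp"] > 0).all()
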