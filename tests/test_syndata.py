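"""Synthetic-data generator: determinism, LD structure, liability model,
ascertainment and annotation properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathprs import syndata
from pathprs.syndata import AscertainmentError, SimulationConfig


def adjacent_r2(genotypes, within_block_only=True):
    D = genotypes.dosages.astype(float)
    blk = genotypes.variants["BLOCK"].to_numpy()
    vals = []
    for j in range(1, genotypes.n_variants):
        same = blk[j] == blk[j - 1]
        if same == within_block_only:
            vals.append(np.corrcoef(D[:, j], D[:, j - 1])[0, 1] ** 2)
    return np.asarray(vals)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n_individuals": 0},
        {"n_variants": 0},
        {"within_block_corr": 1.0},
        {"maf_range": (0.0, 0.5)},
        {"maf_range": (0.1, 0.6)},
        {"n_causal": 10_000},
        {"heritability_target": 1.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestGenotypes:
    def test_deterministic_given_seed(self, small_config, small_genotypes):
        again = syndata.simulate_genotypes(small_config)
        np.testing.assert_array_equal(again.dosages, small_genotypes.dosages)
        pd.testing.assert_frame_equal(again.variants, small_genotypes.variants)

    def test_dosages_are_hard_calls(self, small_genotypes):
        assert set(np.unique(small_genotypes.dosages)) <= {0.0, 1.0, 2.0}

    def test_positions_strictly_increasing_per_chromosome(self, small_genotypes):
        for _, sub in small_genotypes.variants.groupby("CHR"):
            assert (np.diff(sub["BP"]) > 0).all()

    def test_zero_correlation_gives_independent_variants(self):
        cfg = SimulationConfig(n_individuals=3000, n_variants=200, n_blocks=5,
                               n_causal=20, within_block_corr=0.0, seed=3)
        g = syndata.simulate_genotypes(cfg)
        r2 = adjacent_r2(g)
        # mean |r| for independent pairs is ~1/sqrt(n); r2 ~ 1/n
        assert r2.mean() < 5.0 / 3000

    def test_high_correlation_gives_strong_adjacent_ld(self):
        cfg = SimulationConfig(n_individuals=2000, n_variants=500, n_blocks=10,
                               within_block_corr=0.9, seed=7)
        g = syndata.simulate_genotypes(cfg)
        assert adjacent_r2(g).mean() > 0.5

    def test_blocks_are_mutually_independent(self):
        cfg = SimulationConfig(n_individuals=2000, n_variants=400, n_blocks=20,
                               within_block_corr=0.9, seed=9)
        g = syndata.simulate_genotypes(cfg)
        cross = adjacent_r2(g, within_block_only=False)
        assert cross.mean() < 5.0 / 2000

    def test_empirical_maf_tracks_configured_maf(self, small_genotypes):
        freq = small_genotypes.dosages.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        target = small_genotypes.variants["MAF"].to_numpy()
        n = small_genotypes.n_samples
        se = np.sqrt(target * (1 - target) / (2 * n))
        # all simulated MAFs within 5 binomial SEs of their target
        assert (np.abs(maf - np.minimum(target, 1 - target)) < 5 * se + 0.01).all()

    def test_validation_cohort_shares_variant_panel(self, small_config, small_genotypes):
        val = syndata.simulate_validation_genotypes(small_config, small_genotypes,
                                                    300, seed=99)
        pd.testing.assert_frame_equal(val.variants, small_genotypes.variants)
        assert val.n_samples == 300
        assert not np.array_equal(val.dosages[:300], small_genotypes.dosages[:300])


class TestBaseGwas:
    def test_null_variants_give_uniform_pvalues(self, small_genotypes):
        null_model = syndata.draw_true_model(small_genotypes.variants, n_causal=0,
                                             effect_sd=0.0, seed=1)
        ss = syndata.simulate_base_gwas(small_genotypes, null_model,
                                        n_base=100_000, seed=2)
        frac = (ss["P"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(ss))

    def test_estimates_converge_to_true_betas(self, small_genotypes):
        tm = syndata.draw_true_model(small_genotypes.variants, n_causal=50,
                                     effect_sd=0.1, seed=4)
        ss = syndata.simulate_base_gwas(small_genotypes, tm, n_base=10**10, seed=5)
        est = ss.set_index("SNP")
        for snp, beta in zip(tm.causal_ids, tm.true_betas):
            row = est.loc[snp]
            signed = row["BETA"] if row["A1"] == small_genotypes.variants.set_index(
                "SNP").loc[snp, "ALT"] else -row["BETA"]
            assert signed == pytest.approx(beta, abs=1e-3)

    def test_seed_reproducibility(self, small_genotypes):
        tm = syndata.draw_true_model(small_genotypes.variants, 10, 0.05, seed=6)
        a = syndata.simulate_base_gwas(small_genotypes, tm, 50_000, seed=8)
        b = syndata.simulate_base_gwas(small_genotypes, tm, 50_000, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_small_n_base_rejected(self, small_genotypes):
        tm = syndata.draw_true_model(small_genotypes.variants, 5, 0.05, seed=1)
        with pytest.raises(ValueError):
            syndata.simulate_base_gwas(small_genotypes, tm, n_base=1, seed=0)


class TestPhenotype:
    def test_controls_older_than_minimum(self, small_config, small_genotypes):
        tm = syndata.draw_true_model(small_genotypes.variants, 60, 0.05, seed=2)
        cohort = syndata.simulate_phenotype(small_genotypes, tm, small_config)
        controls = cohort[cohort["STATUS"] == 0]
        cases = cohort[cohort["STATUS"] == 1]
        assert (controls["AGE"] > small_config.control_min_age).all()
        assert (cases["AGE"] < small_config.case_def_age).all()

    def test_null_model_prevalence_matches_configuration(self):
        cfg = SimulationConfig(n_individuals=4000, n_variants=50, n_blocks=2,
                               n_causal=0, heritability_target=0.0,
                               covariate_effects={"sex": 0.0, "bmi": 0.0},
                               prevalence=0.3, seed=21)
        g = syndata.simulate_genotypes(cfg)
        tm = syndata.draw_true_model(g.variants, 0, 0.0, seed=1)
        syndata.simulate_phenotype(g, tm, cfg)
        # pre-ascertainment hypertensive fraction is the configured prevalence
        frac = (tm.liability > np.quantile(tm.liability, 1 - cfg.prevalence)).mean()
        assert frac == pytest.approx(0.3, abs=0.01)

    def test_heritability_recovered_from_liability(self, small_config, small_genotypes):
        tm = syndata.draw_true_model(small_genotypes.variants, 60, 0.05, seed=3)
        syndata.simulate_phenotype(small_genotypes, tm, small_config)
        g = tm.genetic_score
        r2 = np.corrcoef(tm.liability, g)[0, 1] ** 2
        assert r2 == pytest.approx(small_config.heritability_target, abs=1e-6)

    def test_ascertained_controls_depleted_of_risk_alleles(self, small_config,
                                                           small_genotypes):
        tm = syndata.draw_true_model(small_genotypes.variants, 60, 0.05, seed=4)
        cohort = syndata.simulate_phenotype(small_genotypes, tm, small_config)
        pop_mean = tm.genetic_score.mean()
        control_mean = cohort.loc[cohort["STATUS"] == 0, "G_TRUE"].mean()
        case_mean = cohort.loc[cohort["STATUS"] == 1, "G_TRUE"].mean()
        assert control_mean < pop_mean < case_mean

    def test_impossible_ascertainment_reported(self, small_genotypes):
        cfg = SimulationConfig(n_individuals=600, n_variants=800, n_blocks=20,
                               n_causal=10, case_def_age=0.0,
                               control_min_age=200.0, seed=11)
        tm = syndata.draw_true_model(small_genotypes.variants, 10, 0.05, seed=1)
        with pytest.raises(AscertainmentError):
            syndata.simulate_phenotype(small_genotypes, tm, cfg)


class TestAnnotation:
    def test_no_intergenic_means_every_variant_in_one_gene(self, small_genotypes):
        bed, _ = syndata.simulate_annotation(small_genotypes.variants, n_genes=40,
                                             n_pathways=5, pathway_size_range=(3, 10),
                                             frac_intergenic=0.0, seed=5)
        from pathprs.pathway import map_snps_to_genes
        mapping = map_snps_to_genes(small_genotypes.variants, bed)
        assert len(mapping) == small_genotypes.n_variants
        assert all(len(genes) == 1 for genes in mapping.values())

    def test_gene_set_count_and_sizes(self, small_genotypes):
        _, sets = syndata.simulate_annotation(small_genotypes.variants, n_genes=250,
                                              n_pathways=186,
                                              pathway_size_range=(10, 200),
                                              frac_intergenic=0.3, seed=6)
        assert len(sets) == 186
        assert all(10 <= len(g) <= 200 for g in sets.values())

    def test_intergenic_fraction_respected(self, small_genotypes):
        bed, _ = syndata.simulate_annotation(small_genotypes.variants, n_genes=40,
                                             n_pathways=5, pathway_size_range=(3, 10),
                                             frac_intergenic=0.3, seed=7)
        from pathprs.pathway import map_snps_to_genes
        mapping = map_snps_to_genes(small_genotypes.variants, bed)
        genic_frac = len(mapping) / small_genotypes.n_variants
        assert genic_frac == pytest.approx(0.7, abs=0.05)

    def test_gene_intervals_do_not_overlap(self, small_genotypes):
        bed, _ = syndata.simulate_annotation(small_genotypes.variants, n_genes=40,
                                             n_pathways=5, pathway_size_range=(3, 10),
                                             frac_intergenic=0.2, seed=8)
        for _, sub in bed.groupby("CHR"):
            sub = sub.sort_values("START")
            assert (sub["START"].to_numpy()[1:] >= sub["END"].to_numpy()[:-1]).all()

    def test_oversized_pathway_range_rejected(self, small_genotypes):
        with pytest.raises(ValueError):
            syndata.simulate_annotation(small_genotypes.variants, n_genes=10,
                                        n_pathways=3, pathway_size_range=(5, 50),
                                        frac_intergenic=0.2, seed=9)

    def test_seed_reproducibility(self, small_genotypes):
        out1 = syndata.simulate_annotation(small_genotypes.variants, 30, 8,
                                           (3, 10), 0.2, seed=10)
        out2 = syndata.simulate_annotation(small_genotypes.variants, 30, 8,
                                           (3, 10), 0.2, seed=10)
        pd.testing.assert_frame_equal(out1[0], out2[0])
        assert out1[1] == out2[1]


class TestWriters:
    def test_vcf_roundtrip_hard_calls(self, tmp_path):
        cfg = SimulationConfig(n_individuals=30, n_variants=40, n_blocks=4, seed=13,
                               n_causal=5)
        g = syndata.simulate_genotypes(cfg)
        path = tmp_path / "g.vcf"
        syndata.write_vcf(g, path)
        from pathprs.io import read_vcf
        back = read_vcf(path)
        np.testing.assert_array_equal(back.dosages, g.dosages)
        assert list(back.variants["SNP"]) == list(g.variants["SNP"])

    def test_written_files_deterministic(self, tmp_path):
        cfg = SimulationConfig(n_individuals=20, n_variants=30, n_blocks=3,
                               n_causal=5, seed=17)
        texts = []
        for sub in ("a", "b"):
            g = syndata.simulate_genotypes(cfg)
            p = tmp_path / f"{sub}.vcf"
            syndata.write_vcf(g, p)
            texts.append(p.read_text())
        assert texts[0] == texts[1]
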