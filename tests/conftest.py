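"""Shared fixtures: small synthetic studies and hand-built file fixtures."""

import numpy as np
import pandas as pd
import pytest

from pathprs import pipeline, syndata
from pathprs.containers import GenotypeData, HarmonizedPanel


@pytest.fixture(scope="session")
def small_config():
    return syndata.SimulationConfig(
        n_individuals=600, n_variants=800, n_blocks=20, n_causal=60,
        heritability_target=0.4, seed=11,
    )


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return syndata.simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_study():
    """A compact end-to-end dataset shared by integration-style tests."""
    return pipeline.simulate_dataset(
        5, n_individuals=700, n_variants=1200, n_blocks=30, n_causal=100,
        heritability=0.4, n_genes=60, n_pathways=12, pathway_size_range=(5, 15),
        two_cohorts=True, n_validation=700,
    )


def random_panel(rng, n_variants, n_individuals=60, n_chrom=1, max_span=600_000):
    """A random harmonized panel + matching genotypes for oracle checks."""
    chrom = rng.integers(1, n_chrom + 1, size=n_variants)
    pos = rng.integers(1, max_span, size=n_variants)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    # ensure unique positions per chromosome
    for c in np.unique(chrom):
        mask = chrom == c
        pos[mask] = np.sort(pos[mask]) + np.arange(mask.sum())
    variants = pd.DataFrame({
        "SNP": [f"v{i}" for i in range(n_variants)],
        "CHR": chrom.astype(str),
        "BP": pos,
        "REF": ["A"] * n_variants,
        "ALT": ["G"] * n_variants,
    })
    # correlated-ish genotypes: mixture of shared and independent Bernoulli draws
    base = rng.integers(0, 3, size=(n_individuals, n_variants)).astype(float)
    for j in range(1, n_variants):
        share = rng.random()
        if share < 0.4:
            copy_from = rng.integers(0, j)
            rows = rng.random(n_individuals) < 0.8
            base[rows, j] = base[rows, copy_from]
    # avoid monomorphic columns
    for j in range(n_variants):
        if np.std(base[:, j]) == 0:
            base[0, j] = (base[0, j] + 1) % 3
    geno = GenotypeData(dosages=base, variants=variants,
                        samples=[f"s{i}" for i in range(n_individuals)])
    panel = HarmonizedPanel(variants=variants.assign(
        EFFECT_ALLELE="G", OTHER_ALLELE="A",
        BETA=rng.normal(0, 0.1, n_variants),
        P=rng.random(n_variants),
        FLIP=False,
    ))
    return panel, geno


def brute_force_clump(panel_df, dosages, window_kb, r2_max):
    """Straight-line re-implementation of the greedy clumping rule.

    Independent of the vectorised implementation: explicit loops, pairwise
    correlations one at a time.
    """
    entries = panel_df.reset_index(drop=True)
    order = sorted(range(len(entries)),
                   key=lambda i: (entries["P"][i], str(entries["CHR"][i]),
                                  entries["BP"][i]))
    assigned = set()
    index_ids = []
    members = {}
    for i in order:
        if i in assigned:
            continue
        assigned.add(i)
        index_ids.append(entries["SNP"][i])
        absorbed = []
        for j in range(len(entries)):
            if j in assigned:
                continue
            if str(entries["CHR"][j]) != str(entries["CHR"][i]):
                continue
            if abs(int(entries["BP"][j]) - int(entries["BP"][i])) > window_kb * 1000:
                continue
            r = np.corrcoef(dosages[:, i], dosages[:, j])[0, 1]
            if r * r > r2_max:
                assigned.add(j)
                absorbed.append(entries["SNP"][j])
        members[entries["SNP"][i]] = absorbed
    return index_ids, members


def has_knife_edge_pair(dosages, r2_max, tol=1e-6):
    """True when some pairwise r² sits at the strict-inequality boundary,
    where algebraically equivalent correlation computations (float32 dosage
    storage vs float64 recomputation) can disagree about '> r2_max'."""
    dosages = np.asarray(dosages, dtype=np.float64)
    Z = (dosages - dosages.mean(0)) / dosages.std(0)
    R = (Z.T @ Z) / len(dosages)
    r2 = R**2
    np.fill_diagonal(r2, np.inf)
    return bool((np.abs(r2 - r2_max) < tol).any())


def pairwise_auc(scores, status):
    """AUC by exhaustive case-control pair enumeration (ties count 1/2)."""
    scores = np.asarray(scores, float)
    status = np.asarray(status, int)
    cases = scores[status == 1]
    controls = scores[status == 0]
    total = 0.0
    for x in cases:
        for y in controls:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(cases) * len(controls))


def stepup_bh(pvals):
    """Hand-traced Benjamini-Hochberg step-up."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
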