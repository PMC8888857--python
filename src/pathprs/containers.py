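"""In-memory containers shared across pipeline stages.

The genotype matrix is dense (individuals x variants, effect-allele dosage
0-2); cohorts of a few thousand individuals by a few hundred thousand
variants fit comfortably in memory as float32, which is the scale this
pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns of a variant table. MAF is optional (simulator provides it).
VARIANT_COLUMNS = ["SNP", "CHR", "BP", "REF", "ALT"]

#: Columns of a base summary-statistics table.
SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "P"]


@dataclass
class GenotypeData:
    """Dosage matrix plus its variant panel and sample identifiers.

    ``dosages[i, j]`` counts copies of the ALT allele of variant ``j``
    carried by individual ``i`` (hard calls in {0,1,2} or imputed dosages
    in [0,2]; missing calls are NaN until QC imputes them).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (individuals x variants)")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} dosage rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant rows for {m} dosage columns")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, snp_ids) -> np.ndarray:
        """Column indices of the given variant IDs (raises on unknowns)."""
        lookup = pd.Index(self.variants["SNP"])
        idx = lookup.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"variants not in genotype panel: {missing[:5]}...")
        return idx

    def take_variants(self, indices) -> "GenotypeData":
        indices = np.asarray(indices)
        return GenotypeData(
            dosages=self.dosages[:, indices],
            variants=self.variants.iloc[indices].reset_index(drop=True),
            samples=list(self.samples),
        )

    def take_samples(self, sample_ids) -> "GenotypeData":
        pos = pd.Index(self.samples).get_indexer(list(sample_ids))
        if (pos < 0).any():
            raise KeyError("sample ids missing from genotype data")
        return GenotypeData(
            dosages=self.dosages[pos, :],
            variants=self.variants,
            samples=list(sample_ids),
        )


@dataclass
class TrueModel:
    """Ground-truth generative model behind a synthetic dataset.

    Used only by parameter-recovery tests and the simulator itself; no
    analysis stage may look at it.
    """

    causal_ids: list[str]
    true_betas: np.ndarray  # per-ALT-allele liability effects, aligned to causal_ids
    liability: np.ndarray | None = None  # per-individual latent score, filled by the phenotype stage
    genetic_score: np.ndarray | None = None

    def beta_vector(self, variant_table: pd.DataFrame) -> np.ndarray:
        """Dense per-variant effect vector aligned to ``variant_table``."""
        beta = pd.Series(0.0, index=variant_table["SNP"])
        missing = set(self.causal_ids) - set(beta.index)
        if missing:
            raise ValueError(f"causal ids absent from variant panel: {sorted(missing)[:5]}")
        beta.loc[list(self.causal_ids)] = np.asarray(self.true_betas, dtype=float)
        return beta.to_numpy()


@dataclass
class HarmonizedPanel:
    """Base summary statistics reconciled with the target variant panel.

    ``variants`` carries SNP/CHR/BP/BETA/P plus a boolean FLIP column:
    the stored beta always weights the target ALT dosage after applying
    ``2 - dosage`` wherever FLIP is set, i.e. the panel is oriented so
    every weight counts the base study's effect allele.
    """

    variants: pd.DataFrame
    n_input: int = 0
    n_kept: int = 0
    n_flipped: int = 0
    n_palindromic: int = 0
    n_unmatched: int = 0
    n_mismatched: int = 0

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.variants)

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_flipped": self.n_flipped,
            "n_palindromic_dropped": self.n_palindromic,
            "n_unmatched": self.n_unmatched,
            "n_allele_mismatch_dropped": self.n_mismatched,
        }


@dataclass
class ClumpResult:
    """Outcome of greedy p-value-ordered LD clumping."""

    index_variants: pd.DataFrame  # retained panel rows, p non-decreasing
    clump_members: dict = field(default_factory=dict)  # index SNP -> absorbed SNP list

    @property
    def n_index(self) -> int:
        return len(self.index_variants)


@dataclass
class PRSProfile:
    """Per-individual scores across a p-value threshold grid."""

    scores: pd.DataFrame  # index: IID, one column per threshold
    n_variants_used: dict  # threshold -> count

    @property
    def thresholds(self) -> list[float]:
        return list(self.scores.columns)
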