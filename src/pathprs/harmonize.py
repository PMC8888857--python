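"""Reconcile base summary statistics with the target variant panel.

Variants are matched by (chromosome, position) with allele verification:
when the base effect allele equals the target ALT the weight applies to
the stored dosage directly; when it equals REF the record is flagged for
flipping (effect dosage = 2 − stored dosage); when the base alleles only
match after strand complementation the same rule applies to the
complemented pair. Palindromic variants (A/T, C/G) are strand-ambiguous
and dropped, as are records whose alleles cannot be reconciled at all.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from pathprs.containers import GenotypeData, HarmonizedPanel
from pathprs.syndata import COMPLEMENT

logger = logging.getLogger(__name__)

__all__ = ["harmonize", "qc_filter", "compute_pcs", "HarmonizationError"]


class HarmonizationError(RuntimeError):
    pass


def _is_palindromic(a: str, b: str) -> bool:
    return COMPLEMENT.get(a) == b


def harmonize(base: pd.DataFrame, target: pd.DataFrame) -> HarmonizedPanel:
    """Match base summary statistics to target variants and orient alleles.

    Parameters
    ----------
    base : summary statistics with SNP/CHR/BP/A1/A2/BETA/P (A1 = effect allele).
    target : variant table with SNP/CHR/BP/REF/ALT.

    Returns a :class:`HarmonizedPanel` whose BETA weights count the base
    effect allele on the target dosage scale, with a FLIP flag marking
    records where the effect allele is the target REF.
    """
    if base.empty or target.empty:
        raise HarmonizationError("base summary statistics and target panel must be non-empty")

    tgt = target[["SNP", "CHR", "BP", "REF", "ALT"]].copy()
    tgt["CHR"] = tgt["CHR"].astype(str)
    bs = base.copy()
    bs["CHR"] = bs["CHR"].astype(str)

    merged = bs.merge(tgt, on=["CHR", "BP"], how="inner", suffixes=("_base", ""))
    n_unmatched = len(bs) - len(merged)

    kept_rows = []
    n_pal = n_mismatch = n_flip = 0
    for row in merged.itertuples(index=False):
        ref, alt = row.REF, row.ALT
        a1, a2 = row.A1, row.A2
        if _is_palindromic(ref, alt):
            n_pal += 1
            continue
        if {a1, a2} == {ref, alt}:
            pass
        elif {COMPLEMENT.get(a1, "?"), COMPLEMENT.get(a2, "?")} == {ref, alt}:
            a1, a2 = COMPLEMENT[a1], COMPLEMENT[a2]
        else:
            n_mismatch += 1
            continue
        flip = a1 == ref
        if flip:
            n_flip += 1
        kept_rows.append(
            {"SNP": row.SNP, "CHR": row.CHR, "BP": row.BP, "REF": ref, "ALT": alt,
             "EFFECT_ALLELE": a1, "OTHER_ALLELE": a2,
             "BETA": row.BETA, "P": row.P, "FLIP": flip}
        )

    panel = pd.DataFrame(kept_rows)
    if not panel.empty:
        # at most one record per (chrom, pos, allele pair)
        panel = panel.drop_duplicates(subset=["CHR", "BP", "REF", "ALT"], keep="first")
    if panel.empty:
        raise HarmonizationError("no variant survived harmonization")

    result = HarmonizedPanel(
        variants=panel,
        n_input=len(bs),
        n_kept=len(panel),
        n_flipped=int(panel["FLIP"].sum()) if not panel.empty else 0,
        n_palindromic=n_pal,
        n_unmatched=max(n_unmatched, 0),
        n_mismatched=n_mismatch,
    )
    logger.info("harmonize: %s", result.summary())
    return result


def qc_filter(genotypes: GenotypeData, maf_min: float = 0.01,
              call_rate_min: float = 0.95) -> GenotypeData:
    """Drop variants failing MAF or call-rate cutoffs; mean-impute the rest.

    MAF is computed from the mean dosage over non-missing calls. After
    filtering, remaining missing dosages are imputed to the variant mean
    (the conventional C+T choice); the operation is idempotent.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not (0 <= call_rate_min <= 1):
        raise ValueError("call_rate_min must lie in [0, 1]")

    dos = genotypes.dosages
    call_rate = 1.0 - np.isnan(dos).mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = (call_rate >= call_rate_min) & (maf >= maf_min) & ~np.isnan(maf)
    if not keep.any():
        raise HarmonizationError("QC removed every variant")

    out = genotypes.take_variants(np.flatnonzero(keep))
    dos = out.dosages
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dos))
        dos[nan_r, nan_c] = col_mean[nan_c].astype(dos.dtype)
    logger.info("qc_filter: kept %d / %d variants", out.n_variants, genotypes.n_variants)
    return out


def compute_pcs(genotypes: GenotypeData | np.ndarray, k: int = 4) -> pd.DataFrame:
    """Principal components of the column-standardized dosage matrix.

    Components are ordered by explained variance and sign-fixed so the
    largest-magnitude variant loading of each component is positive,
    making outputs comparable across runs.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if isinstance(genotypes, GenotypeData):
        X = genotypes.dosages
        index = list(genotypes.samples)
    else:
        X = np.asarray(genotypes, dtype=float)
        index = list(range(X.shape[0]))
    n, m = X.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n_individuals, n_variants)={min(n, m)}")

    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    # economy SVD: deterministic, exact; cohort-scale matrices are small
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=index,
                        columns=[f"PC{i + 1}" for i in range(k)])
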