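"""LD clumping and clumping+thresholding polygenic scores.

Clumping is the greedy index-SNP procedure: repeatedly take the
unassigned variant with the smallest base-GWAS p-value as an index, and
absorb every unassigned variant within the flanking window whose r² with
the index exceeds the LD threshold, so each variant belongs to at most
one clump. LD is the squared Pearson correlation of dosage vectors,
computed on the target cohort's own genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pathprs.containers import ClumpResult, GenotypeData, HarmonizedPanel, PRSProfile

logger = logging.getLogger(__name__)

__all__ = ["ClumpParams", "DEFAULT_THRESHOLDS", "ld_r2", "clump", "score",
           "threshold_scan"]

#: p-value threshold grid scanned for the genome-wide score, from the
#: full model (no filtering) down to genome-wide significance.
DEFAULT_THRESHOLDS = (1.0, 0.5, 0.05, 1e-4, 1e-6, 5e-8)


@dataclass
class ClumpParams:
    """window: flanking distance in kb (±window around the index variant);
    r2_max: variants with r² strictly greater than this are absorbed."""

    window: float = 250.0
    r2_max: float = 0.1

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive (kb)")
        if not (0 <= self.r2_max <= 1):
            raise ValueError("r2_max must lie in [0, 1]")


def ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("dosage vectors must be 1-D and of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 individuals to estimate LD")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant dosage vector (monomorphic variant); run QC first")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(panel: HarmonizedPanel, genotypes: GenotypeData,
          params: ClumpParams | None = None) -> ClumpResult:
    """Greedy p-value-ordered LD clumping of the harmonized panel.

    Ties on p are broken by (chromosome, position) so runs are
    deterministic. Returns the retained index variants in processing
    order (p non-decreasing) and the absorbed members of each clump.
    """
    params = params or ClumpParams()
    pv = panel.variants
    if pv.empty:
        raise ValueError("cannot clump an empty panel")

    cols = genotypes.variant_index(pv["SNP"])
    X = np.asarray(genotypes.dosages[:, cols], dtype=np.float64)
    n = X.shape[0]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = pv["SNP"].iloc[np.flatnonzero(sd == 0)[:5]].tolist()
        raise ValueError(f"monomorphic variants in panel (run QC first): {bad}")
    Z = (X - mu) / sd

    chrom = pv["CHR"].astype(str).to_numpy()
    pos = pv["BP"].to_numpy()
    p = pv["P"].to_numpy()
    window_bp = params.window * 1000.0

    # per-chromosome position-sorted views for windowed neighbour lookup
    order_by_pos: dict[str, np.ndarray] = {}
    for c in np.unique(chrom):
        rows = np.flatnonzero(chrom == c)
        order_by_pos[c] = rows[np.argsort(pos[rows], kind="stable")]

    proc_order = np.lexsort((pos, chrom, p))  # smallest p first; (chrom, pos) tie-break
    assigned = np.zeros(len(pv), dtype=bool)
    index_rows: list[int] = []
    members: dict[str, list[str]] = {}

    for i in proc_order:
        if assigned[i]:
            continue
        assigned[i] = True
        index_rows.append(i)
        rows_c = order_by_pos[chrom[i]]
        pos_c = pos[rows_c]
        lo = np.searchsorted(pos_c, pos[i] - window_bp, side="left")
        hi = np.searchsorted(pos_c, pos[i] + window_bp, side="right")
        cand = rows_c[lo:hi]
        cand = cand[~assigned[cand]]
        if cand.size:
            r = Z[:, cand].T @ Z[:, i] / n
            absorbed = cand[r * r > params.r2_max]
            assigned[absorbed] = True
            members[pv["SNP"].iloc[i]] = pv["SNP"].iloc[absorbed].tolist()
        else:
            members[pv["SNP"].iloc[i]] = []

    result = ClumpResult(
        index_variants=pv.iloc[index_rows].reset_index(drop=True),
        clump_members=members,
    )
    logger.info("clump: %d index variants from %d (window ±%g kb, r² > %g absorbs)",
                result.n_index, len(pv), params.window, params.r2_max)
    return result


def score(genotypes: GenotypeData, clump_result: ClumpResult,
          thresholds=DEFAULT_THRESHOLDS) -> PRSProfile:
    """Weighted-allele-sum PRS at each p-value threshold.

    score_i(t) = Σ_{j: p_j ≤ t} β_j · d_ij where d_ij counts the base
    effect allele (2 − stored dosage for FLIP-flagged variants). The
    variant set at a stricter threshold is nested in every looser one.
    """
    thresholds = sorted({float(t) for t in thresholds}, reverse=True)
    if any(not (0 < t <= 1) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    iv = clump_result.index_variants
    idx = genotypes.variant_index(iv["SNP"])
    D = np.asarray(genotypes.dosages[:, idx], dtype=np.float64)
    flip = iv["FLIP"].to_numpy(dtype=bool) if "FLIP" in iv else np.zeros(len(iv), bool)
    D_eff = np.where(flip[None, :], 2.0 - D, D)
    beta = iv["BETA"].to_numpy(dtype=float)
    p = iv["P"].to_numpy(dtype=float)

    cols = {}
    n_used = {}
    for t in thresholds:
        mask = p <= t
        n_used[t] = int(mask.sum())
        if n_used[t] == 0:
            logger.warning("score: no variant passes p <= %g; scores set to 0", t)
            cols[t] = np.zeros(D.shape[0])
        else:
            cols[t] = D_eff[:, mask] @ beta[mask]
    scores = pd.DataFrame(cols, index=pd.Index(genotypes.samples, name="IID"))
    return PRSProfile(scores=scores, n_variants_used=n_used)


def threshold_scan(profile: PRSProfile, cohort: pd.DataFrame,
                   covariates: pd.DataFrame | None = None):
    """Fit the association model at every threshold; pick the best by
    partial Nagelkerke R².

    Returns ``(best_threshold, table)`` where the table holds one row per
    threshold (n_variants, beta per SD of PRS, SE, p, r2_full, r2_cov,
    partial_r2, converged) — the data behind the model-fit bar plot.
    Non-convergent thresholds are reported and excluded from the argmax.
    """
    from pathprs import assoc  # local import: assoc does not depend on clumpscore

    rows = []
    for t in profile.thresholds:
        prs = profile.scores[t].reindex(cohort["IID"]).to_numpy()
        entry = {"threshold": t, "n_variants": profile.n_variants_used[t]}
        try:
            res = assoc.prs_association(prs, cohort, covariates)
            entry.update(beta=res.beta_prs, se=res.se, p=res.p_value,
                         r2_full=res.r2_full, r2_cov=res.r2_cov,
                         partial_r2=res.partial_r2, converged=True)
        except assoc.FitError as exc:
            logger.warning("threshold_scan: fit failed at p <= %g: %s", t, exc)
            entry.update(beta=np.nan, se=np.nan, p=np.nan, r2_full=np.nan,
                         r2_cov=np.nan, partial_r2=np.nan, converged=False)
        rows.append(entry)
    table = pd.DataFrame(rows)
    fitted = table[table["converged"]]
    if fitted.empty:
        raise RuntimeError("no threshold produced a convergent fit")
    best = float(fitted.loc[fitted["partial_r2"].idxmax(), "threshold"])
    return best, table
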