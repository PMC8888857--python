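"""Case/control association of polygenic scores.

Covariate-adjusted logistic regression (status ~ PRS + sex + BMI + PCs),
partial Nagelkerke pseudo-R² (full-model R² minus covariate-only R²),
decile odds-ratio stratification against the median decile, ROC/AUC and
the paired DeLong test comparing the full and covariate-only models.
Age is deliberately not a covariate: the extreme-ascertainment design
(early-onset cases, old normotensive controls) makes its distribution
bimodal and perfectly confounded with status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = ["FitError", "FitResult", "AssociationResult", "RocComparison",
           "fit_logistic", "newton_logit", "nagelkerke_r2", "prs_association",
           "build_design", "decile_table", "odds_ratio_2x2", "roc_auc",
           "delong_test",
           "DEFAULT_COVARIATES"]

#: covariates of the association model (plus the first PCs when supplied)
DEFAULT_COVARIATES = ("SEX", "BMI")


class FitError(RuntimeError):
    """Logistic fit failed (separation, rank deficiency, non-convergence)."""


@dataclass
class FitResult:
    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    n: int

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))


@dataclass
class AssociationResult:
    """PRS association summary. ``beta_prs`` is log-odds per SD of PRS."""

    beta_prs: float
    se: float
    p_value: float
    loglik_full: float
    loglik_cov: float
    loglik_null: float
    r2_full: float
    r2_cov: float
    partial_r2: float
    n: int


@dataclass
class RocComparison:
    auc_full: float
    auc_cov: float
    delong_p: float
    z: float
    var_diff: float
    degenerate: bool = False


def fit_logistic(status, design_matrix) -> FitResult:
    """Maximum-likelihood logistic fit via statsmodels.

    ``design_matrix`` must already contain the intercept column.
    Raises :class:`FitError` on separation or non-convergence rather than
    returning a silently unreliable fit.
    """
    y = np.asarray(status, dtype=float)
    X = np.asarray(design_matrix, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank deficient")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # PerfectSeparationError and numerical failures
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    if np.any(res.bse > 1e3):
        raise FitError("implausible standard errors suggest (quasi-)separation")
    return FitResult(params=np.asarray(res.params), bse=np.asarray(res.bse),
                     llf=float(res.llf), converged=True, n=len(y))


def newton_logit(y, X, start=None, tol: float = 1e-10, maxiter: int = 50):
    """Plain Newton-Raphson logistic MLE (warm-startable).

    Used in permutation inner loops where thousands of small fits are
    needed; agrees with :func:`fit_logistic` to numerical precision (the
    test suite asserts this). Returns (beta, cov, llf, converged).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    beta = np.zeros(k) if start is None else np.array(start, dtype=float)
    llf_old = -np.inf
    cov = None
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        llf = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return beta, None, llf, False
        step = cov @ grad
        beta_new = beta + step
        if not np.all(np.isfinite(beta_new)):
            return beta, cov, llf, False
        if abs(llf - llf_old) < tol and np.max(np.abs(step)) < 1e-8:
            return beta_new, cov, llf, True
        beta, llf_old = beta_new, llf
    return beta, cov, llf_old, False


def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Nagelkerke pseudo-R²: Cox-Snell R² rescaled to a [0, 1] maximum.

    R²_CS = 1 − exp(−(2/n)(ll_model − ll_null));
    R²_N  = R²_CS / (1 − exp((2/n)·ll_null)).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_model < loglik_null - 1e-8:
        raise ValueError("model log-likelihood below null (models not nested?)")
    r2_cs = 1.0 - np.exp(-(2.0 / n) * (loglik_model - loglik_null))
    max_cs = 1.0 - np.exp((2.0 / n) * loglik_null)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(r2_cs / max_cs, 0.0, 1.0))


def build_design(cohort: pd.DataFrame, covariates: pd.DataFrame | None = None,
                 covar_names=DEFAULT_COVARIATES) -> np.ndarray:
    """Intercept + cohort covariate columns + any extra columns (e.g. PCs)."""
    parts = [np.ones(len(cohort))]
    for c in covar_names:
        parts.append(cohort[c].to_numpy(dtype=float))
    if covariates is not None:
        if covariates.index.equals(pd.RangeIndex(len(covariates))):
            extra = covariates
            if len(extra) != len(cohort):
                raise ValueError("positional covariates must match cohort length")
        else:
            extra = covariates.reindex(cohort["IID"])
            if extra.isna().any().any():
                raise ValueError("covariates missing for some cohort individuals")
        parts.extend(extra[c].to_numpy(dtype=float) for c in extra.columns)
    return np.column_stack(parts)


def prs_association(prs, cohort: pd.DataFrame,
                    covariates: pd.DataFrame | None = None,
                    covar_names=DEFAULT_COVARIATES) -> AssociationResult:
    """Fit full, covariate-only and intercept-only models; report the
    partial Nagelkerke R² attributable to the (standardized) PRS."""
    y = cohort["STATUS"].to_numpy(dtype=float)
    prs = np.asarray(prs, dtype=float)
    if prs.std() == 0:
        raise FitError("PRS is constant in this cohort")
    prs_std = (prs - prs.mean()) / prs.std()

    X_cov = build_design(cohort, covariates, covar_names)
    X_full = np.column_stack([X_cov, prs_std])
    n = len(y)

    full = fit_logistic(y, X_full)
    cov_only = fit_logistic(y, X_cov)
    null = fit_logistic(y, np.ones((n, 1)))

    r2_full = nagelkerke_r2(full.llf, null.llf, n)
    r2_cov = nagelkerke_r2(cov_only.llf, null.llf, n)
    return AssociationResult(
        beta_prs=float(full.params[-1]),
        se=float(full.bse[-1]),
        p_value=float(full.pvalues[-1]),
        loglik_full=full.llf,
        loglik_cov=cov_only.llf,
        loglik_null=null.llf,
        r2_full=r2_full,
        r2_cov=r2_cov,
        partial_r2=r2_full - r2_cov,
        n=n,
    )


def assign_deciles(prs) -> np.ndarray:
    """Decile labels 1..10 by empirical PRS quantiles (1 = lowest scores);
    ties broken by stable input order."""
    prs = np.asarray(prs, dtype=float)
    n = len(prs)
    rank = stats.rankdata(prs, method="ordinal")  # stable for ties
    return np.ceil(rank * 10.0 / n).astype(int)


def odds_ratio_2x2(n_cases: float, n_controls: float,
                   ref_cases: float, ref_controls: float) -> dict:
    """Crude odds ratio of one stratum against a reference stratum.

    OR = (cases·ref_controls)/(controls·ref_cases), Wald 95% CI from
    SE = sqrt(Σ 1/cell), two-sided normal p. Zero cells receive a 0.5
    continuity correction and are flagged.
    """
    cells = np.array([n_cases, n_controls, ref_cases, ref_controls], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = np.sqrt(np.sum(1.0 / cells))
    z = np.log(or_) / se
    return {
        "odds_ratio": float(or_),
        "ci_low": float(np.exp(np.log(or_) - 1.959963984540054 * se)),
        "ci_high": float(np.exp(np.log(or_) + 1.959963984540054 * se)),
        "p_value": float(2.0 * stats.norm.sf(abs(z))),
        "continuity_corrected": corrected,
    }


def decile_table(prs, cohort: pd.DataFrame, reference_decile: int = 5) -> pd.DataFrame:
    """Crude odds ratios for case status per PRS decile vs the reference.

    Each decile forms a 2×2 table against the reference (median) decile;
    OR is the cross-product ratio with a Wald 95% CI from
    SE = sqrt(Σ 1/cell) and a two-sided normal p. Zero cells get a 0.5
    continuity correction and are flagged.
    """
    if len(cohort) < 10:
        raise ValueError("need at least 10 individuals for deciles")
    status = cohort["STATUS"].to_numpy(dtype=int)
    dec = assign_deciles(prs)
    ref_cases = int(((dec == reference_decile) & (status == 1)).sum())
    ref_controls = int(((dec == reference_decile) & (status == 0)).sum())
    if ref_cases == 0 or ref_controls == 0:
        raise ValueError("reference decile must contain both cases and controls")

    rows = []
    for d in range(1, 11):
        cases = int(((dec == d) & (status == 1)).sum())
        controls = int(((dec == d) & (status == 0)).sum())
        if d == reference_decile:
            rows.append({"decile": d, "n_cases": cases, "n_controls": controls,
                         "odds_ratio": 1.0, "ci_low": 1.0, "ci_high": 1.0,
                         "p_value": 1.0, "continuity_corrected": False})
            continue
        rows.append({"decile": d, "n_cases": cases, "n_controls": controls,
                     **odds_ratio_2x2(cases, controls, ref_cases, ref_controls)})
    return pd.DataFrame(rows)


def roc_auc(risk_scores, status) -> float:
    """AUC: probability a random case outranks a random control (mid-rank
    tie convention)."""
    y = np.asarray(status, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(risk_scores, dtype=float)))


def _placements(scores: np.ndarray, status: np.ndarray):
    """Per-case and per-control placement values (ties count 1/2)."""
    x = scores[status == 1]
    y = scores[status == 0]
    gt = (x[:, None] > y[None, :]).astype(float)
    eq = (x[:, None] == y[None, :]).astype(float)
    psi = gt + 0.5 * eq
    return psi.mean(axis=1), psi.mean(axis=0)  # V10 (cases), V01 (controls)


def delong_test(pred_full, pred_cov, status) -> RocComparison:
    """Paired DeLong test for the difference of two correlated AUCs.

    Placement values of each model give empirical AUCs; their covariance
    across cases and controls yields var(AUC_full − AUC_cov); z is the
    standardized difference with a two-sided normal p. Identical
    predictions (zero variance) return p = 1 and are flagged.
    """
    y = np.asarray(status, dtype=int)
    f = np.asarray(pred_full, dtype=float)
    c = np.asarray(pred_cov, dtype=float)
    if f.shape != c.shape or f.shape != y.shape:
        raise ValueError("prediction vectors and status must share one length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    v10_f, v01_f = _placements(f, y)
    v10_c, v01_c = _placements(c, y)
    auc_f, auc_c = float(v10_f.mean()), float(v10_c.mean())
    m, n = len(v10_f), len(v01_f)

    s10 = np.cov(np.vstack([v10_f, v10_c]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_f, v01_c]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n

    if var <= 0:
        degenerate = True
        z = 0.0
        p = 1.0
        if not np.allclose(f, c):
            logger.warning("delong_test: zero variance of AUC difference; p set to 1")
    else:
        degenerate = False
        z = (auc_f - auc_c) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return RocComparison(auc_full=auc_f, auc_cov=auc_c, delong_p=p, z=float(z),
                         var_diff=float(var), degenerate=degenerate)
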