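"""Statistical machinery: Wilcoxon rank-sum with AUC, BH adjustment,
a negative-binomial Wald test for replicated bulk counts, Spearman
correlation, and a categorical linear model.

The rank-sum test reports the AUC ``U / (n_a * n_b)``, the probability that
a random observation from group A exceeds one from group B (ties counted as
half).  P-values use a tie-corrected normal approximation with continuity
correction, switching to exact enumeration of all label assignments when the
pooled sample size is at most ``EXACT_MAX_N``.

The bulk differential test is a deliberately simple two-group NB GLM:
median-of-ratios size factors, per-region method-of-moments dispersion
(no empirical-Bayes shrinkage), an IRLS fit with log link, and a Wald test
on the condition coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .normalize import NormalizedMatrix, median_ratio_size_factors

EXACT_MAX_N = 12
LOG2FC_EPS = 1e-9
DISPERSION_FLOOR_QUANTILE = 0.6


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum / AUC
# ---------------------------------------------------------------------------


def _rank_sum_U(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U of group a vs b with midranks, plus the tie term."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    r_a = ranks[:n_a].sum()
    u = r_a - n_a * (n_a + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    return float(u), tie_term


def rank_sum_auc(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float, float]:
    """Wilcoxon rank-sum test of a vs b; returns ``(U, auc, p)``.

    ``auc = P(A > B) + 0.5 * P(A = B)``.  ``alternative='greater'`` tests for
    stochastically larger values in ``a``.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    u, tie_term = _rank_sum_U(a, b)
    auc = u / (n_a * n_b)
    if n_a + n_b <= EXACT_MAX_N:
        p = _exact_permutation_p(a, b, u, alternative)
    else:
        p = _normal_approx_p(u, n_a, n_b, tie_term, alternative)
    return u, auc, p


def _exact_permutation_p(
    a: np.ndarray, b: np.ndarray, u_obs: float, alternative: str
) -> float:
    """Enumerate all C(n_a+n_b, n_a) group assignments of the pooled values."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    n_a = len(a)
    offset = n_a * (n_a + 1) / 2.0
    mid = n_a * (n - n_a) / 2.0
    total = comb(n, n_a)
    hits = 0
    tol = 1e-9
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        if alternative == "greater":
            hits += u >= u_obs - tol
        elif alternative == "less":
            hits += u <= u_obs + tol
        else:
            hits += abs(u - mid) >= abs(u_obs - mid) - tol
    return hits / total


def _normal_approx_p(
    u: float, n_a: int, n_b: int, tie_term: float, alternative: str
) -> float:
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return 1.0
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (u - mu - 0.5) / sd
        return float(sps.norm.sf(z))
    if alternative == "less":
        z = (u - mu + 0.5) / sd
        return float(sps.norm.cdf(z))
    z = (abs(u - mu) - 0.5) / sd
    return float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return padj


# ---------------------------------------------------------------------------
# per-feature differential testing (single-cell)
# ---------------------------------------------------------------------------


def differential_features(
    norm_matrix: NormalizedMatrix,
    labels: Sequence[str],
    target_group: str,
    min_cells_expressed: int = 0,
) -> pd.DataFrame:
    """Two-sided rank-sum test of ``target_group`` vs all other cells, per feature.

    ``avg_log2fc`` compares group means of de-logged normalized values
    (``expm1`` of the log1p-normalized signal) with a small pseudocount.
    Returns a DataFrame with columns feature_id, avg_log2fc, auc, p, padj,
    group, indexed like the input features (minus any min-cells filter).
    """
    labels = np.asarray(labels)
    if len(labels) != norm_matrix.n_cells:
        raise ValueError("one label per cell required")
    in_target = labels == target_group
    if in_target.sum() < 2 or (~in_target).sum() < 2:
        raise ValueError("need >= 2 cells in the target group and in the rest")
    dense = norm_matrix.to_dense()
    if min_cells_expressed > 0:
        expressed = (dense > 0).sum(axis=1) >= min_cells_expressed
    else:
        expressed = np.ones(dense.shape[0], dtype=bool)
    rows = np.flatnonzero(expressed)
    delogged = np.expm1(dense)
    recs = []
    for i in rows:
        vals = dense[i]
        u, auc, p = rank_sum_auc(vals[in_target], vals[~in_target])
        m_t = delogged[i, in_target].mean()
        m_r = delogged[i, ~in_target].mean()
        lfc = np.log2((m_t + LOG2FC_EPS) / (m_r + LOG2FC_EPS))
        recs.append((norm_matrix.feature_ids[i], lfc, auc, p))
    out = pd.DataFrame(recs, columns=["feature_id", "avg_log2fc", "auc", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["group"] = target_group
    return out


def differential_deviations(
    deviations: pd.DataFrame, labels: Sequence[str], target_group: str
) -> pd.DataFrame:
    """Rank-sum differential test on motif deviation z-scores.

    ``deviations`` is motifs x cells.  Because z-scores may be negative, the
    effect size is the difference of group means (``delta``) rather than a
    fold change.
    """
    labels = np.asarray(labels)
    if len(labels) != deviations.shape[1]:
        raise ValueError("one label per cell required")
    in_target = labels == target_group
    if in_target.sum() < 2 or (~in_target).sum() < 2:
        raise ValueError("need >= 2 cells in the target group and in the rest")
    vals = deviations.to_numpy(dtype=float)
    recs = []
    for i, motif in enumerate(deviations.index):
        u, auc, p = rank_sum_auc(vals[i, in_target], vals[i, ~in_target])
        delta = vals[i, in_target].mean() - vals[i, ~in_target].mean()
        recs.append((motif, delta, auc, p))
    out = pd.DataFrame(recs, columns=["feature_id", "delta", "auc", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["group"] = target_group
    return out


# ---------------------------------------------------------------------------
# NB Wald differential for replicated bulk counts
# ---------------------------------------------------------------------------


def nb_wald_differential(
    bulk_counts: pd.DataFrame,
    condition_labels: Sequence[str],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Two-condition NB Wald test on a regions x samples count table.

    Size factors come from median-of-ratios.  Per-region dispersion is
    method-of-moments on within-condition residuals of the normalized
    counts (so a real condition effect does not inflate its own dispersion),
    ``alpha_i = max((s_resid^2 - mean) / mean_sq, 1e-8)``, then floored at
    the 60th percentile of the across-region dispersions — a conservative
    moderation that stops the handful-of-replicates estimate from
    collapsing to zero and keeps the Wald tail near nominal.  The
    two-group log-link NB GLM is fit by vectorized IRLS with the size factor
    as offset, and the condition coefficient is tested with a two-sided Wald
    z.  All-zero regions are reported with NaN statistics and excluded from
    BH.
    """
    counts = np.asarray(bulk_counts, dtype=float)
    region_ids = [str(r) for r in bulk_counts.index]
    labels = np.asarray([str(c) for c in condition_labels])
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"exactly two conditions required, got {list(levels)}")
    for lvl in levels:
        if (labels == lvl).sum() < 2:
            raise ValueError(f"condition {lvl!r} has < 2 replicates")
    g = (labels == levels[1]).astype(float)  # second level is the tested effect

    sf = median_ratio_size_factors(counts)
    norm = counts / sf
    in_b = g == 1
    mu_a = norm[:, ~in_b].mean(axis=1)
    mu_b = norm[:, in_b].mean(axis=1)
    resid = norm.copy()
    resid[:, ~in_b] -= mu_a[:, None]
    resid[:, in_b] -= mu_b[:, None]
    s2 = (resid**2).sum(axis=1) / max(norm.shape[1] - 2, 1)
    mean_mu = (mu_a + mu_b) / 2.0
    mean_mu_sq = (mu_a**2 + mu_b**2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mean_mu_sq > 0, (s2 - mean_mu) / mean_mu_sq, 0.0)
    alpha = np.maximum(alpha, 1e-8)
    alpha = np.maximum(alpha, np.quantile(alpha, DISPERSION_FLOOR_QUANTILE))

    nonzero = counts.sum(axis=1) > 0
    beta0, beta1, se1 = _nb_irls_two_group(
        counts[nonzero], sf, g, alpha[nonzero], max_iter=max_iter, tol=tol
    )
    z = beta1 / se1
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    lfc = beta1 / np.log(2.0)

    out = pd.DataFrame(
        {
            "feature_id": region_ids,
            "log2fc": np.nan,
            "baseMean": norm.mean(axis=1),
            "stat": np.nan,
            "p": np.nan,
            "padj": np.nan,
        }
    )
    out.loc[nonzero, "log2fc"] = lfc
    out.loc[nonzero, "stat"] = z
    out.loc[nonzero, "p"] = p
    out.loc[nonzero, "padj"] = bh_adjust(p)
    out["group"] = levels[1]
    out.attrs["conditions"] = (str(levels[0]), str(levels[1]))
    out.attrs["size_factors"] = sf
    out.attrs["dispersion"] = "method-of-moments, no shrinkage"
    return out


def _nb_irls_two_group(
    y: np.ndarray,
    sf: np.ndarray,
    g: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for ``log mu = log sf + b0 + b1*g`` with fixed NB dispersion.

    Operates on all regions at once; returns (b0, b1, se(b1)).
    """
    n_regions = y.shape[0]
    log_sf = np.log(sf)
    norm = y / sf
    in_b = g == 1
    # init from group means of normalized counts (pseudocount keeps logs finite)
    m_a = norm[:, ~in_b].mean(axis=1) + 0.5
    m_b = norm[:, in_b].mean(axis=1) + 0.5
    b0 = np.log(m_a)
    b1 = np.log(m_b) - np.log(m_a)
    alpha = alpha[:, None]
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * g[None, :]
        mu = np.exp(eta + log_sf[None, :])
        mu = np.clip(mu, 1e-10, 1e12)
        w = mu / (1.0 + alpha * mu)
        zwork = eta + (y - mu) / mu
        # closed-form WLS for design [1, g]: g binary so g^2 = g
        s0 = w.sum(axis=1)
        s1 = (w * g).sum(axis=1)
        t0 = (w * zwork).sum(axis=1)
        t1 = (w * zwork * g).sum(axis=1)
        det = s1 * (s0 - s1)
        det = np.where(det > 0, det, np.nan)
        new_b1 = (s0 * t1 - s1 * t0) / det
        new_b0 = (t0 - s1 * new_b1) / s0
        new_b0 = np.clip(np.nan_to_num(new_b0, nan=0.0), -30, 30)
        new_b1 = np.clip(np.nan_to_num(new_b1, nan=0.0), -30, 30)
        delta = np.max(np.abs(new_b0 - b0)) + np.max(np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        if delta < tol:
            break
    eta = b0[:, None] + b1[:, None] * g[None, :]
    mu = np.clip(np.exp(eta + log_sf[None, :]), 1e-10, 1e12)
    w = mu / (1.0 + alpha * mu)
    s0 = w.sum(axis=1)
    s1 = (w * g).sum(axis=1)
    det = s1 * (s0 - s1)
    var_b1 = np.where(det > 0, s0 / det, np.inf)  # [ (X'WX)^-1 ]_11
    return b0, b1, np.sqrt(var_b1)


# ---------------------------------------------------------------------------
# correlation and linear model
# ---------------------------------------------------------------------------


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for a constant vector")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


@dataclass
class ConditionModelResult:
    """OLS fit of scores on a categorical condition."""

    reference: str
    coefficients: pd.DataFrame  # index: level; columns: coef, se, t, p
    f_stat: float
    f_p: float
    n_obs: int

    def coef(self, level: str) -> pd.Series:
        return self.coefficients.loc[level]


def ols_condition_test(
    scores: Sequence[float], condition_labels: Sequence[str], reference: str | None = None
) -> ConditionModelResult:
    """OLS of per-observation scores on dummy-coded condition levels.

    Each non-reference level gets a coefficient (its mean shift from the
    reference) with a two-sided t-test; the overall F tests all levels
    jointly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = pd.Series([str(c) for c in condition_labels])
    if len(scores) != len(labels):
        raise ValueError("scores and labels must align")
    counts = labels.value_counts()
    if (counts < 2).any():
        thin = list(counts[counts < 2].index)
        raise ValueError(f"levels with < 2 observations: {thin}")
    if len(counts) < 2:
        raise ValueError("need >= 2 condition levels")
    levels = list(pd.unique(labels))
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among conditions")
    others = [lvl for lvl in levels if lvl != reference]
    X = np.column_stack([np.ones(len(labels))] + [(labels == lvl).to_numpy(float) for lvl in others])
    fit = sm.OLS(scores, X).fit()
    coef = pd.DataFrame(
        {
            "coef": fit.params[1:],
            "se": fit.bse[1:],
            "t": fit.tvalues[1:],
            "p": fit.pvalues[1:],
        },
        index=others,
    )
    return ConditionModelResult(
        reference=reference,
        coefficients=coef,
        f_stat=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        n_obs=int(fit.nobs),
    )
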