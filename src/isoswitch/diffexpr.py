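"""Per-cluster differential expression between timepoints.

A deliberately simple, transparent engine: median-of-ratios size factors,
log2 fold change of pseudo-counted normalized means, a t test on
log2(normalized + 0.5) replicate values, and Benjamini-Hochberg adjustment
across clusters.  A cluster is called significantly up at log2fc >= 1 and
adjusted p < 0.05 (down symmetric at <= -1); these are the calls the
switching and internal-isoform analyses consume.

With two or three replicates a per-cluster variance estimate has so few
degrees of freedom that even large, real inductions cannot reach
BH-surviving p-values; the matrix-level driver therefore moderates each
cluster's pooled variance toward a common prior estimated from all
clusters (classical empirical-Bayes shrinkage of scaled-inverse-chi-square
variances), gaining the prior's degrees of freedom.  The un-moderated
per-cluster Welch test remains available (``moderate=False`` or
:func:`test_cluster` directly).  Externally computed results (e.g. a
DESeq2 table with cluster_id, log2fc, padj) can be substituted anywhere a
DiffResult table is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiffResult",
    "size_factors",
    "test_cluster",
    "adjust_bh",
    "run_differential_expression",
]

PSEUDOCOUNT = 0.5
LOG2FC_THRESHOLD = 1.0
PADJ_THRESHOLD = 0.05


@dataclass
class DiffResult:
    cluster_id: str
    comparison: str
    log2fc: float
    p: Optional[float]
    padj: Optional[float] = None

    @property
    def significant_up(self) -> bool:
        return (
            self.padj is not None
            and not np.isnan(self.padj)
            and self.log2fc >= LOG2FC_THRESHOLD
            and self.padj < PADJ_THRESHOLD
        )

    @property
    def significant_down(self) -> bool:
        return (
            self.padj is not None
            and not np.isnan(self.padj)
            and self.log2fc <= -LOG2FC_THRESHOLD
            and self.padj < PADJ_THRESHOLD
        )


def size_factors(count_matrix: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors, one per sample (column).

    factor_j = median over rows i (restricted to rows with positive
    geometric mean) of count_ij / geometric_mean_i.
    """
    counts = np.asarray(count_matrix, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a clusters x samples matrix with >= 2 samples")
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    finite = np.all(np.isfinite(log_counts), axis=1)
    if not finite.any():
        raise ValueError(
            "no cluster has nonzero counts in every sample; consider a "
            "pseudo-reference fallback"
        )
    log_geomean = log_counts[finite].mean(axis=1)
    ratios = np.exp(log_counts[finite] - log_geomean[:, None])
    return np.median(ratios, axis=0)


def test_cluster(
    counts_t: Sequence[float],
    counts_ref: Sequence[float],
    factors_t: Sequence[float],
    factors_ref: Sequence[float],
    cluster_id: str = "",
    comparison: str = "",
    pseudocount: float = PSEUDOCOUNT,
) -> DiffResult:
    """Differential test for one cluster between two replicate groups.

    Fold change uses pseudo-counted means of normalized counts:
    log2((mean_T + c) / (mean_ref + c)), c = 0.5.  The p-value comes from a
    two-sided Welch t test on log2(normalized + c) per replicate.  With
    fewer than 2 replicates in either group p is None; when both groups are
    exactly constant the test degenerates and p is 1 for equal means, 0
    otherwise.
    """
    t = np.asarray(counts_t, dtype=float) / np.asarray(factors_t, dtype=float)
    r = np.asarray(counts_ref, dtype=float) / np.asarray(factors_ref, dtype=float)
    log2fc = float(np.log2((t.mean() + pseudocount) / (r.mean() + pseudocount)))
    if len(t) < 2 or len(r) < 2:
        return DiffResult(cluster_id, comparison, log2fc, None)
    lt = np.log2(t + pseudocount)
    lr = np.log2(r + pseudocount)
    if np.allclose(lt.std(), 0) and np.allclose(lr.std(), 0):
        p = 1.0 if np.isclose(lt.mean(), lr.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(lt, lr, equal_var=False).pvalue)
    return DiffResult(cluster_id, comparison, log2fc, p)


def adjust_bh(p_values: Sequence[Optional[float]]) -> np.ndarray:
    """Benjamini-Hochberg step-up over the non-missing p-values.

    Missing entries (None/NaN) stay NaN in the output and do not count
    toward the number of tests.
    """
    arr = np.array(
        [np.nan if p is None else float(p) for p in p_values], dtype=float
    )
    valid = ~np.isnan(arr)
    if np.any((arr[valid] < 0) | (arr[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(len(arr), np.nan)
    if valid.sum():
        out[valid] = multipletests(arr[valid], method="fdr_bh")[1]
    return out


def _inverse_trigamma(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (Smyth 2004, appendix)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def moderated_variances(
    variances: np.ndarray,
    df: int,
    abundance: Optional[np.ndarray] = None,
    max_prior_df: float = 100.0,
) -> Tuple[np.ndarray, float]:
    """Shrink per-cluster variances toward a count-level-aware prior.

    The prior follows the Gamma-Poisson mean-variance relation of log
    counts, var ~ a + b / mean, fitted across clusters (so low-count
    clusters shrink toward an appropriately larger prior); the prior
    degrees of freedom d0 come from matching the moments of
    log(s_i^2 / trend_i) against the scaled-inverse-chi-square model.
    Returns the posterior variances (d0 trend + df s^2) / (d0 + df) and d0.
    """
    s2 = np.asarray(variances, dtype=float)
    ok = s2 > 0
    if ok.sum() < 3:
        return s2, 0.0
    if abundance is not None:
        x = 1.0 / np.maximum(np.asarray(abundance, dtype=float), 1e-6)
        X = np.column_stack([np.ones(ok.sum()), x[ok]])
        coef, *_ = np.linalg.lstsq(X, s2[ok], rcond=None)
        a, b = max(float(coef[0]), 0.0), max(float(coef[1]), 0.0)
        trend = np.maximum(a + b * x, np.percentile(s2[ok], 5))
    else:
        trend = np.full_like(s2, float(np.median(s2[ok])))
    z = np.log(s2[ok] / trend[ok])
    var_z = float(np.var(z, ddof=1))
    excess = var_z - float(special.polygamma(1, df / 2.0))
    if excess <= 1e-8:
        d0 = max_prior_df
    else:
        d0 = min(2.0 * _inverse_trigamma(excess), max_prior_df)
    # scale the trend so E[log(s^2/prior)] matches the chi-square model
    e_z = float(np.mean(z))
    s0_scale = float(
        np.exp(
            e_z
            - float(special.digamma(df / 2.0))
            + float(special.digamma(d0 / 2.0))
            + np.log(df / d0)
        )
    )
    prior = trend * s0_scale
    posterior = (d0 * prior + df * s2) / (d0 + df)
    return posterior, d0


def run_differential_expression(
    counts: pd.DataFrame,
    samples_t: Sequence[str],
    samples_ref: Sequence[str],
    comparison: str = "",
    moderate: bool = True,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """DE over all clusters for one comparison.

    ``counts`` is a clusters x samples DataFrame of raw counts (index =
    cluster_id).  Size factors are estimated from all involved samples
    jointly; with ``moderate=True`` (default) per-cluster pooled variances
    are shrunk toward the common prior before the t test, otherwise each
    cluster is tested independently by Welch's t.  BH adjustment spans all
    tested clusters of the comparison.
    """
    cols = list(samples_t) + list(samples_ref)
    mat = counts[cols].to_numpy(dtype=float)
    factors = size_factors(mat)
    n_t, n_r = len(samples_t), len(samples_ref)
    norm = mat / factors[None, :]
    t_norm, r_norm = norm[:, :n_t], norm[:, n_t:]
    log2fc = np.log2(
        (t_norm.mean(axis=1) + pseudocount) / (r_norm.mean(axis=1) + pseudocount)
    )

    if moderate and n_t >= 2 and n_r >= 2:
        lt = np.log2(t_norm + pseudocount)
        lr = np.log2(r_norm + pseudocount)
        df_resid = n_t + n_r - 2
        pooled = (
            lt.var(axis=1, ddof=1) * (n_t - 1) + lr.var(axis=1, ddof=1) * (n_r - 1)
        ) / df_resid
        abundance = norm.mean(axis=1) + pseudocount
        post_var, d0 = moderated_variances(pooled, df_resid, abundance)
        se = np.sqrt(np.maximum(post_var, 1e-12) * (1.0 / n_t + 1.0 / n_r))
        tstat = (lt.mean(axis=1) - lr.mean(axis=1)) / se
        p_arr = 2.0 * stats.t.sf(np.abs(tstat), df_resid + d0)
        p_list = [float(p) for p in p_arr]
    else:
        p_list = []
        for i in range(mat.shape[0]):
            res = test_cluster(
                mat[i, :n_t],
                mat[i, n_t:],
                factors[:n_t],
                factors[n_t:],
                pseudocount=pseudocount,
            )
            p_list.append(res.p)

    padj = adjust_bh(p_list)
    df = pd.DataFrame(
        {
            "cluster_id": [str(c) for c in counts.index],
            "comparison": comparison,
            "log2fc": log2fc,
            "p": [np.nan if p is None else p for p in p_list],
            "padj": padj,
        }
    )
    df["significant_up"] = (
        (df.log2fc >= LOG2FC_THRESHOLD) & (df.padj < PADJ_THRESHOLD)
    ).fillna(False)
    df["significant_down"] = (
        (df.log2fc <= -LOG2FC_THRESHOLD) & (df.padj < PADJ_THRESHOLD)
    ).fillna(False)
    return df
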