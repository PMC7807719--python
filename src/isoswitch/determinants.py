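"""Determinants of main-TSS repression by upstream alternative transcription.

For genes whose upstream alternative TSS is >= 2-fold induced in one
aggregated transition comparison, a determinant record collects the
apex-to-apex pair distance, the alternative's post-transition level
(log2(TPM + 0.5)), the main TSS's pre-transition TPM, the main TSS's log2
fold change (the response), and an externally supplied per-gene nucleosome
occupancy-change covariate.  Records split at an 80-bp pair distance,
compare distributions by Pearson and two-sample Kolmogorov-Smirnov tests,
and feed a three-predictor OLS fit whose per-variable effect sizes are
semi-partial correlations (the correlation between the response and the
part of each predictor orthogonal to the others).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .switching import DiffLookup, TssPair, _sig_up

__all__ = [
    "DeterminantRecord",
    "RegressionFit",
    "build_determinant_table",
    "split_by_distance",
    "correlate_and_test",
    "subset_by_levels",
    "fit_multiple_regression",
]

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DeterminantRecord:
    gene_id: str
    transition: str
    pair_distance: int
    alt_level: float  # log2(TPM + 0.5) after transition
    main_prior_level: float  # TPM before transition
    main_log2fc: float  # response variable
    occupancy_change: float


@dataclass
class RegressionFit:
    coefficients: Dict[str, float]
    adjusted_r2: float
    r2: float
    semi_partial: Dict[str, float]
    p_values: Dict[str, float]
    n: int


def build_determinant_table(
    pairs: Sequence[TssPair],
    diff: DiffLookup,
    comparison_timepoint: str,
    reference_timepoint: str,
    occupancy: Mapping[str, float],
    seed: int = 0,
) -> List[DeterminantRecord]:
    """One record per gene with a qualifying (2-fold-up) upstream alternative.

    When several alternatives of one gene qualify, a single one is chosen at
    random under the fixed seed, so the table is reproducible.  Genes whose
    main cluster has no DE result in the aggregated comparison are skipped.
    """
    rng = np.random.default_rng(seed)
    by_gene: Dict[str, List[TssPair]] = {}
    for pair in pairs:
        if pair.pair_distance <= 0:
            continue
        if _sig_up(diff.get(comparison_timepoint, pair.alt_cluster_id)):
            by_gene.setdefault(pair.gene_id, []).append(pair)
    records: List[DeterminantRecord] = []
    for gene_id in sorted(by_gene):
        qualifying = sorted(by_gene[gene_id], key=lambda p: p.alt_cluster_id)
        pair = qualifying[int(rng.integers(len(qualifying)))]
        main_row = diff.get(comparison_timepoint, pair.main_cluster_id)
        if main_row is None:
            continue
        records.append(
            DeterminantRecord(
                gene_id=gene_id,
                transition=pair.transition,
                pair_distance=pair.pair_distance,
                alt_level=float(
                    np.log2(pair.alt_tpm.get(comparison_timepoint, 0.0) + PSEUDOCOUNT)
                ),
                main_prior_level=pair.main_tpm.get(reference_timepoint, 0.0),
                main_log2fc=float(main_row["log2fc"]),
                occupancy_change=float(occupancy.get(gene_id, 0.0)),
            )
        )
    return records


def split_by_distance(
    records: Sequence[DeterminantRecord], threshold: int = 80
) -> Tuple[List[DeterminantRecord], List[DeterminantRecord]]:
    """(proximal, distal) split: pair distance < threshold vs >= threshold."""
    proximal = [r for r in records if r.pair_distance < threshold]
    distal = [r for r in records if r.pair_distance >= threshold]
    return proximal, distal


def correlate_and_test(
    records: Sequence[DeterminantRecord],
    x_field: str = "pair_distance",
    log2_x: bool = True,
    other: Optional[Sequence[DeterminantRecord]] = None,
) -> Dict[str, float]:
    """Pearson correlation of main_log2fc against one determinant, plus —
    when ``other`` is given — a two-sample KS test between the two groups'
    main_log2fc distributions."""
    out: Dict[str, float] = {}
    if len(records) >= 3:
        x = np.array([getattr(r, x_field) for r in records], dtype=float)
        if log2_x:
            x = np.log2(x)
        y = np.array([r.main_log2fc for r in records])
        if np.std(x) == 0 or np.std(y) == 0:
            out["pearson_r"] = float("nan")
            out["pearson_p"] = float("nan")
        else:
            r, p = stats.pearsonr(x, y)
            out["pearson_r"] = float(r)
            out["pearson_p"] = float(p)
    if other is not None and len(records) >= 3 and len(other) >= 3:
        a = np.array([r.main_log2fc for r in records])
        b = np.array([r.main_log2fc for r in other])
        ks = stats.ks_2samp(a, b, method="asymp")
        out["ks_D"] = float(ks.statistic)
        out["ks_p"] = float(ks.pvalue)
    return out


def _nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th smallest value."""
    if len(values) == 0:
        raise ValueError("empty values")
    srt = np.sort(values)
    if pct <= 0:
        return float(srt[0])
    rank = int(np.ceil(pct / 100.0 * len(srt)))
    return float(srt[min(rank, len(srt)) - 1])


def subset_by_levels(
    records: Sequence[DeterminantRecord],
    alt_pct: float = 50.0,
    main_pct: float = 50.0,
) -> List[DeterminantRecord]:
    """Records with relatively high alternative level and relatively low
    prior main level: alt_level >= its ``alt_pct`` percentile and
    main_prior_level <= its ``main_pct`` percentile (both inclusive,
    nearest-rank percentiles over the given records)."""
    if not records:
        return []
    alt = np.array([r.alt_level for r in records])
    main = np.array([r.main_prior_level for r in records])
    alt_cut = -np.inf if alt_pct <= 0 else _nearest_rank_percentile(alt, alt_pct)
    main_cut = np.inf if main_pct >= 100 else _nearest_rank_percentile(main, main_pct)
    if main_pct >= 100:
        main_cut = np.inf
    return [
        r
        for r in records
        if r.alt_level >= alt_cut and r.main_prior_level <= main_cut
    ]


def fit_multiple_regression(
    records: Sequence[DeterminantRecord],
    predictors: Sequence[str] = ("alt_level", "log2_distance", "occupancy_change"),
    condition_tol: float = 1e8,
) -> RegressionFit:
    """OLS of main_log2fc on the determinants, with semi-partial correlations.

    ``log2_distance`` is derived as log2(pair_distance); ``distance`` uses
    the raw nt value.  For each predictor X_i, sr_i is the correlation
    between the response and the residual of X_i regressed on the other
    predictors (with intercept); sr_i^2 equals the drop in R^2 when X_i is
    removed from the full model.  p-values are the OLS coefficient t-test
    p-values, which test exactly these unique effects.
    """
    n = len(records)
    k = len(predictors)
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} records, got {n}")

    def column(field: str) -> np.ndarray:
        if field == "log2_distance":
            return np.log2(np.array([r.pair_distance for r in records], dtype=float))
        if field == "distance":
            return np.array([r.pair_distance for r in records], dtype=float)
        return np.array([getattr(r, field) for r in records], dtype=float)

    X = np.column_stack([column(f) for f in predictors])
    y = np.array([r.main_log2fc for r in records], dtype=float)
    Xc = sm.add_constant(X)
    if np.linalg.cond(Xc) > condition_tol:
        raise ValueError(
            f"collinear predictors (condition number > {condition_tol:g}): "
            + ", ".join(predictors)
        )
    fit = sm.OLS(y, Xc).fit()
    semi_partial: Dict[str, float] = {}
    for i, name in enumerate(predictors):
        others = np.delete(X, i, axis=1)
        resid = sm.OLS(X[:, i], sm.add_constant(others)).fit().resid
        if np.std(resid) == 0 or np.std(y) == 0:
            semi_partial[name] = float("nan")
        else:
            semi_partial[name] = float(np.corrcoef(y, resid)[0, 1])
    return RegressionFit(
        coefficients={name: float(fit.params[i + 1]) for i, name in enumerate(predictors)},
        adjusted_r2=float(fit.rsquared_adj),
        r2=float(fit.rsquared),
        semi_partial=semi_partial,
        p_values={name: float(fit.pvalues[i + 1]) for i, name in enumerate(predictors)},
        n=n,
    )


def records_to_frame(records: Sequence[DeterminantRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
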