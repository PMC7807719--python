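"""Main/alternative cluster roles and alternative-usage statistics.

Within one cell-fate transition, a gene's *main* TSS (or TES) is its most
highly expressed cluster at the reference timepoint, provided it reaches
1 TPM there; every other assigned cluster reaching 1 TPM at any timepoint
of the transition is an *alternative*.  Alternative usage at a timepoint is
alt / (alt + main) on the TPM scale, so it is invariant under any common
rescaling of a gene's clusters, and the usage change between a transition
timepoint and the reference lies in [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

__all__ = [
    "TransitionConfig",
    "UsageRecord",
    "define_main",
    "define_alternatives",
    "alt_usage",
    "alt_usage_change",
    "build_usage_table",
]


@dataclass(frozen=True)
class TransitionConfig:
    """One cell-fate transition: a reference timepoint and the ordered
    timepoints measured during the transition."""

    name: str
    reference: str
    timepoints: tuple

    def __post_init__(self) -> None:
        if self.reference in self.timepoints:
            raise ValueError("reference timepoint cannot be a transition timepoint")

    @property
    def all_timepoints(self) -> tuple:
        return (self.reference,) + tuple(self.timepoints)


@dataclass
class ClusterExpression:
    """Per-timepoint TPM of one assigned cluster (replicate-averaged)."""

    cluster_id: str
    gene_id: str
    apex: int
    strand: str
    category: str  # upstream | internal | downstream
    tpm: Dict[str, float] = field(default_factory=dict)


@dataclass
class UsageRecord:
    gene_id: str
    transition: str
    cluster_id: str
    role: str  # main | alternative
    tpm: Dict[str, float]
    alt_usage: Dict[str, Optional[float]]
    alt_usage_change: Dict[str, Optional[float]]


def _five_prime_key(c: ClusterExpression):
    return c.apex if c.strand == "+" else -c.apex


def define_main(
    gene_clusters: Sequence[ClusterExpression],
    config: TransitionConfig,
    min_tpm: float = 1.0,
) -> Optional[str]:
    """Main cluster id for this transition: argmax TPM at the reference
    timepoint among clusters with reference TPM >= ``min_tpm``; ties break
    to the 5'-most apex.  None when no cluster qualifies."""
    qualifying = [
        c for c in gene_clusters if c.tpm.get(config.reference, 0.0) >= min_tpm
    ]
    if not qualifying:
        return None
    best = sorted(
        qualifying,
        key=lambda c: (-c.tpm.get(config.reference, 0.0), _five_prime_key(c)),
    )[0]
    return best.cluster_id


def define_alternatives(
    gene_clusters: Sequence[ClusterExpression],
    main: Optional[str],
    config: TransitionConfig,
    min_tpm: float = 1.0,
) -> List[str]:
    """Non-main clusters reaching ``min_tpm`` at >= 1 timepoint of the
    transition (reference included)."""
    out = []
    for c in gene_clusters:
        if c.cluster_id == main:
            continue
        if any(c.tpm.get(tp, 0.0) >= min_tpm for tp in config.all_timepoints):
            out.append(c.cluster_id)
    return out


def alt_usage(alt_tpm_sum: float, main_tpm: float) -> Optional[float]:
    """Alternative usage ratio alt / (alt + main); None when both are zero."""
    total = alt_tpm_sum + main_tpm
    if total <= 0:
        return None
    return alt_tpm_sum / total


def alt_usage_change(
    usage_at_transition: Optional[float], usage_prior: Optional[float]
) -> Optional[float]:
    """Usage difference (transition minus reference), in [-1, 1]."""
    if usage_at_transition is None or usage_prior is None:
        return None
    if math.isnan(usage_at_transition) or math.isnan(usage_prior):
        return None
    return usage_at_transition - usage_prior


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two usage-change samples.

    Uses the exact null distribution when both samples are small (n <= 10)
    and tie-free, the normal approximation otherwise.
    """
    method = (
        "exact"
        if len(x) <= 10 and len(y) <= 10 and len(set(x) | set(y)) == len(x) + len(y)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def build_usage_table(
    clusters_by_gene: Mapping[str, Sequence[ClusterExpression]],
    config: TransitionConfig,
    min_tpm: float = 1.0,
) -> pd.DataFrame:
    """Per-gene usage table for one transition.

    Genes without a definable main at the reference are excluded.  The
    per-gene alternative TPM is the sum over all alternative clusters;
    pairwise (per-cluster) analyses use the raw roles in the output.
    """
    rows = []
    for gene_id, gene_clusters in clusters_by_gene.items():
        main = define_main(gene_clusters, config, min_tpm)
        if main is None:
            continue
        alts = define_alternatives(gene_clusters, main, config, min_tpm)
        by_id = {c.cluster_id: c for c in gene_clusters}
        main_tpm = by_id[main].tpm
        usage_by_tp = {}
        for tp in config.all_timepoints:
            alt_sum = sum(by_id[a].tpm.get(tp, 0.0) for a in alts)
            usage_by_tp[tp] = alt_usage(alt_sum, main_tpm.get(tp, 0.0))
        ref_usage = usage_by_tp[config.reference]
        for tp in config.timepoints:
            rows.append(
                {
                    "gene_id": gene_id,
                    "transition": config.name,
                    "timepoint": tp,
                    "main_cluster": main,
                    "n_alternatives": len(alts),
                    "alt_usage": usage_by_tp[tp],
                    "alt_usage_ref": ref_usage,
                    "alt_usage_change": alt_usage_change(
                        usage_by_tp[tp], ref_usage
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "transition",
            "timepoint",
            "main_cluster",
            "n_alternatives",
            "alt_usage",
            "alt_usage_ref",
            "alt_usage_change",
        ],
    )
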