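"""Differential TSS usage between mutant and control cells at one stage.

Mutant TSS clusters are mapped onto control clusters by >= 1 bp interval
overlap (same strand); per gene and per replicate, raw read counts of the
main TSS versus the summed alternative TSSs form a 2x2 table with genotype
columns, and the replicate-stratified stack is tested with the
Cochran-Mantel-Haenszel statistic (continuity-corrected by default,
chi-square with 1 df).  A gene shows *increased relative expression* of its
main TSS when the CMH adjusted p < 0.05 and the main-read proportion is
larger in the mutant; it is called *de-repressed* when, additionally, in
control cells the main TSS was significantly downregulated while an
upstream alternative TSS was significantly induced (the signature of
repression by upstream transcription).  De-repressed genes are therefore a
subset of the increased-relative-expression genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import SiteCluster
from .diffexpr import adjust_bh

__all__ = [
    "ContingencyStack",
    "DerepressionResult",
    "map_clusters",
    "relative_main_usage",
    "cmh_test",
    "call_derepression",
]


@dataclass
class ContingencyStack:
    """Per-gene stack of replicate 2x2 tables.

    Each stratum is [[main_control, main_mutant], [alt_control, alt_mutant]]
    of raw read counts; strata pair control and mutant replicates by index.
    """

    gene_id: str
    strata: List[np.ndarray] = field(default_factory=list)

    def add_stratum(
        self, main_control: int, main_mutant: int, alt_control: int, alt_mutant: int
    ) -> None:
        tab = np.array(
            [[main_control, main_mutant], [alt_control, alt_mutant]], dtype=float
        )
        if (tab < 0).any():
            raise ValueError("contingency counts must be >= 0")
        self.strata.append(tab)


@dataclass
class DerepressionResult:
    gene_id: str
    cmh_statistic: Optional[float]
    p: Optional[float]
    padj: Optional[float]
    main_usage_control: Optional[float]
    main_usage_mutant: Optional[float]
    increased_relative_expression: bool
    derepressed: bool


def map_clusters(
    mutant_clusters: Sequence[SiteCluster],
    control_clusters: Sequence[SiteCluster],
) -> Dict[str, Optional[str]]:
    """Map each mutant cluster to the control cluster it overlaps.

    Overlap of >= 1 bp on the same contig/strand maps a mutant cluster to a
    control cluster; many-to-one overlaps resolve to the control cluster
    with maximal overlap (ties to the 5'-most control start).  Mutant-only
    clusters map to None and are assigned to genes de novo by the caller.
    """
    by_key: Dict[Tuple[str, str], List[SiteCluster]] = {}
    for c in control_clusters:
        by_key.setdefault((c.contig, c.strand), []).append(c)
    mapping: Dict[str, Optional[str]] = {}
    for m in mutant_clusters:
        best: Optional[SiteCluster] = None
        best_ov = 0
        for c in by_key.get((m.contig, m.strand), []):
            ov = min(m.end, c.end) - max(m.start, c.start)
            if ov <= 0:
                continue
            better = ov > best_ov
            if ov == best_ov and best is not None:
                if m.strand == "+":
                    better = c.start < best.start
                else:
                    better = c.end > best.end
            if better:
                best, best_ov = c, ov
        mapping[m.cluster_id] = best.cluster_id if best else None
    return mapping


def relative_main_usage(
    main_tpm: float, all_cluster_tpms: Sequence[float]
) -> Optional[float]:
    """Main TPM over the summed TPM of all the gene's clusters, in [0, 1].

    Being a within-sample ratio it is invariant under library rescaling.
    None when the gene has no signal at all.
    """
    total = float(sum(all_cluster_tpms))
    if total <= 0:
        return None
    return float(main_tpm) / total


def cmh_test(
    stack: ContingencyStack, continuity: bool = True
) -> Tuple[Optional[float], Optional[float]]:
    """Cochran-Mantel-Haenszel chi-square for a stack of 2x2 strata.

    statistic = (|sum_k (a_k - E_k)| - 1/2 * continuity)^2 / sum_k V_k with
    a_k the main/control cell and E_k, V_k the conditional hypergeometric
    mean and variance given the stratum margins; p from chi-square(1).
    Strata with a zero row or column margin carry no information and are
    dropped; if all are degenerate the result is (None, None).
    """
    num = 0.0
    var = 0.0
    used = 0
    for tab in stack.strata:
        row = tab.sum(axis=1)
        col = tab.sum(axis=0)
        n = tab.sum()
        if n <= 1 or (row == 0).any() or (col == 0).any():
            continue
        a = tab[0, 0]
        e = row[0] * col[0] / n
        v = row[0] * row[1] * col[0] * col[1] / (n * n * (n - 1))
        num += a - e
        var += v
        used += 1
    if used == 0 or var <= 0:
        return None, None
    # the canonical corrected statistic squares the remainder even when
    # |num| < 1/2 (as R's mantelhaen.test does)
    adj = abs(num) - (0.5 if continuity else 0.0)
    statistic = adj * adj / var
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def _pooled_main_proportion(strata: Sequence[np.ndarray], col: int) -> Optional[float]:
    main = sum(t[0, col] for t in strata)
    total = sum(t[:, col].sum() for t in strata)
    if total <= 0:
        return None
    return float(main / total)


def call_derepression(
    stacks: Mapping[str, ContingencyStack],
    control_events: pd.DataFrame,
    continuity: bool = True,
) -> List[DerepressionResult]:
    """Gene-level de-repression calls from CMH results and control events.

    ``control_events`` is the pair-level event table of the control
    time-course at the same stage (from ``run_switching_analysis``); a gene
    counts as repressed-by-upstream-transcription in controls when any of
    its pairs shows main_response == "down" (alternative significantly up
    and main significantly down).
    """
    repressed_in_control = set(
        control_events.loc[
            control_events["main_response"] == "down", "gene_id"
        ].unique()
    )
    gene_ids = sorted(stacks)
    stats_p = []
    for gid in gene_ids:
        stats_p.append(cmh_test(stacks[gid], continuity=continuity))
    padj = adjust_bh([p for _, p in stats_p])
    results: List[DerepressionResult] = []
    for gid, (statistic, p), q in zip(gene_ids, stats_p, padj):
        strata = stacks[gid].strata
        prop_control = _pooled_main_proportion(strata, 0)
        prop_mutant = _pooled_main_proportion(strata, 1)
        qv = None if np.isnan(q) else float(q)
        increased = bool(
            qv is not None
            and qv < 0.05
            and prop_control is not None
            and prop_mutant is not None
            and prop_mutant > prop_control
        )
        results.append(
            DerepressionResult(
                gene_id=gid,
                cmh_statistic=statistic,
                p=p,
                padj=qv,
                main_usage_control=prop_control,
                main_usage_mutant=prop_mutant,
                increased_relative_expression=increased,
                derepressed=increased and gid in repressed_in_control,
            )
        )
    return results
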