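"""Detection of TSS switching and related regulatory events.

For each gene with a defined main TSS, every *strictly upstream, external*
alternative TSS forms a pair with the main TSS.  At a transition timepoint
where the alternative is significantly upregulated (log2fc >= 1, adjusted
p < 0.05), the paired main TSS response is classified as down / up /
unchanged by the same two-fold significance rule.  A *switching event*
additionally requires the alternative's TPM to reach at least the main's
TPM at that timepoint; co-downregulation requires both members of the pair
significantly down.  The same two switching conditions, applied between an
ORF-internal cluster and a promoter cluster of the same gene, call
internal<->promoter switches with a recorded direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .usage import ClusterExpression, TransitionConfig, define_alternatives, define_main

__all__ = [
    "TssPair",
    "SwitchEvent",
    "DiffLookup",
    "build_pairs",
    "classify_main_response",
    "detect_switch",
    "detect_codownregulation",
    "internal_to_promoter_switch",
    "run_switching_analysis",
]

LOG2FC_THRESHOLD = 1.0
PADJ_THRESHOLD = 0.05


class DiffLookup:
    """Per-timepoint differential-expression results indexed by cluster."""

    def __init__(self, tables: Mapping[str, pd.DataFrame]):
        self._tables = {
            tp: df.set_index("cluster_id") if "cluster_id" in df.columns else df
            for tp, df in tables.items()
        }

    def get(self, timepoint: str, cluster_id: str) -> Optional[pd.Series]:
        df = self._tables.get(timepoint)
        if df is None or cluster_id not in df.index:
            return None
        return df.loc[cluster_id]

    def timepoints(self) -> List[str]:
        return list(self._tables)


def _sig_up(row: Optional[pd.Series]) -> bool:
    return (
        row is not None
        and pd.notna(row["padj"])
        and row["log2fc"] >= LOG2FC_THRESHOLD
        and row["padj"] < PADJ_THRESHOLD
    )


def _sig_down(row: Optional[pd.Series]) -> bool:
    return (
        row is not None
        and pd.notna(row["padj"])
        and row["log2fc"] <= -LOG2FC_THRESHOLD
        and row["padj"] < PADJ_THRESHOLD
    )


@dataclass
class TssPair:
    """An upstream external alternative TSS paired with the gene's main TSS."""

    gene_id: str
    transition: str
    alt_cluster_id: str
    main_cluster_id: str
    pair_distance: int
    alt_tpm: Dict[str, float]
    main_tpm: Dict[str, float]


@dataclass
class SwitchEvent:
    gene_id: str
    transition: str
    timepoint: str
    alt_cluster_id: str
    main_cluster_id: str
    main_response: Optional[str]  # down | up | unchanged
    is_switch: bool
    direction: str = "alt_to_main"


def _is_upstream(alt: ClusterExpression, main: ClusterExpression) -> bool:
    if alt.strand == "+":
        return alt.apex < main.apex
    return alt.apex > main.apex


def build_pairs(
    clusters_by_gene: Mapping[str, Sequence[ClusterExpression]],
    config: TransitionConfig,
    min_tpm: float = 1.0,
) -> List[TssPair]:
    """One pair per (gene, strictly-upstream external alternative).

    Internal alternatives are excluded; genes without a definable main at
    the reference timepoint contribute no pairs.
    """
    pairs: List[TssPair] = []
    for gene_id, gene_clusters in clusters_by_gene.items():
        main_id = define_main(gene_clusters, config, min_tpm)
        if main_id is None:
            continue
        by_id = {c.cluster_id: c for c in gene_clusters}
        main = by_id[main_id]
        for alt_id in define_alternatives(gene_clusters, main_id, config, min_tpm):
            alt = by_id[alt_id]
            if alt.category != "upstream" or not _is_upstream(alt, main):
                continue
            pairs.append(
                TssPair(
                    gene_id=gene_id,
                    transition=config.name,
                    alt_cluster_id=alt_id,
                    main_cluster_id=main_id,
                    pair_distance=abs(alt.apex - main.apex),
                    alt_tpm=dict(alt.tpm),
                    main_tpm=dict(main.tpm),
                )
            )
    return pairs


def classify_main_response(
    pair: TssPair, timepoint: str, diff: DiffLookup
) -> Optional[str]:
    """Main-TSS response at a timepoint where the alternative is 2-fold up.

    Returns None (pair skipped) unless the alternative is significantly
    upregulated at this timepoint.
    """
    alt_row = diff.get(timepoint, pair.alt_cluster_id)
    if not _sig_up(alt_row):
        return None
    main_row = diff.get(timepoint, pair.main_cluster_id)
    if _sig_down(main_row):
        return "down"
    if _sig_up(main_row):
        return "up"
    return "unchanged"


def detect_switch(pair: TssPair, timepoint: str, diff: DiffLookup) -> SwitchEvent:
    """Fig-style switching call: alternative 2-fold up (FDR < 0.05) and
    alternative TPM >= main TPM at the same timepoint."""
    alt_row = diff.get(timepoint, pair.alt_cluster_id)
    is_switch = _sig_up(alt_row) and pair.alt_tpm.get(
        timepoint, 0.0
    ) >= pair.main_tpm.get(timepoint, 0.0)
    return SwitchEvent(
        gene_id=pair.gene_id,
        transition=pair.transition,
        timepoint=timepoint,
        alt_cluster_id=pair.alt_cluster_id,
        main_cluster_id=pair.main_cluster_id,
        main_response=classify_main_response(pair, timepoint, diff),
        is_switch=bool(is_switch),
    )


def detect_codownregulation(
    pair: TssPair, timepoint: str, diff: DiffLookup
) -> bool:
    """True when both the alternative and the main TSS are >= 2-fold down
    (adjusted p < 0.05) at this timepoint."""
    return _sig_down(diff.get(timepoint, pair.alt_cluster_id)) and _sig_down(
        diff.get(timepoint, pair.main_cluster_id)
    )


def internal_to_promoter_switch(
    gene_clusters: Sequence[ClusterExpression],
    config: TransitionConfig,
    diff: DiffLookup,
    min_tpm: float = 1.0,
) -> List[SwitchEvent]:
    """Switching between an ORF-internal cluster and a promoter cluster.

    Requires the gene's reference-dominant (main) cluster to be internal
    and at least one upstream promoter cluster, or vice versa; the rising
    cluster must be 2-fold up (FDR < 0.05) and reach the dominant cluster's
    TPM.  The recorded direction names dominant -> rising roles.
    """
    if not gene_clusters:
        return []
    gene_id = gene_clusters[0].gene_id
    main_id = define_main(gene_clusters, config, min_tpm)
    if main_id is None:
        return []
    by_id = {c.cluster_id: c for c in gene_clusters}
    main = by_id[main_id]
    alt_ids = define_alternatives(gene_clusters, main_id, config, min_tpm)
    events: List[SwitchEvent] = []
    for alt_id in alt_ids:
        alt = by_id[alt_id]
        roles = {main.category, alt.category}
        if roles != {"internal", "upstream"}:
            continue
        direction = (
            "internal_to_promoter"
            if main.category == "internal"
            else "promoter_to_internal"
        )
        for tp in config.timepoints:
            alt_row = diff.get(tp, alt_id)
            fired = _sig_up(alt_row) and alt.tpm.get(tp, 0.0) >= main.tpm.get(
                tp, 0.0
            )
            events.append(
                SwitchEvent(
                    gene_id=gene_id,
                    transition=config.name,
                    timepoint=tp,
                    alt_cluster_id=alt_id,
                    main_cluster_id=main_id,
                    main_response=None,
                    is_switch=bool(fired),
                    direction=direction,
                )
            )
    return events


def run_switching_analysis(
    clusters_by_gene: Mapping[str, Sequence[ClusterExpression]],
    config: TransitionConfig,
    diff: DiffLookup,
    min_tpm: float = 1.0,
) -> pd.DataFrame:
    """Pair-level event table across all transition timepoints.

    One row per (pair, timepoint) with the main-response class, the switch
    verdict and the co-downregulation verdict.  Gene/transition-level calls
    aggregate as "any timepoint (any pair) fired".
    """
    pairs = build_pairs(clusters_by_gene, config, min_tpm)
    rows = []
    for pair in pairs:
        for tp in config.timepoints:
            event = detect_switch(pair, tp, diff)
            rows.append(
                {
                    "gene_id": pair.gene_id,
                    "transition": pair.transition,
                    "timepoint": tp,
                    "alt_cluster_id": pair.alt_cluster_id,
                    "main_cluster_id": pair.main_cluster_id,
                    "pair_distance": pair.pair_distance,
                    "alt_tpm": pair.alt_tpm.get(tp, 0.0),
                    "main_tpm": pair.main_tpm.get(tp, 0.0),
                    "main_response": event.main_response,
                    "is_switch": event.is_switch,
                    "codownregulated": detect_codownregulation(pair, tp, diff),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "transition",
            "timepoint",
            "alt_cluster_id",
            "main_cluster_id",
            "pair_distance",
            "alt_tpm",
            "main_tpm",
            "main_response",
            "is_switch",
            "codownregulated",
        ],
    )
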