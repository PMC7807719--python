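"""Assignment of consensus TSS/TES clusters to gene models.

A cluster is assigned to at most one gene — the closest non-overlapping
gene in the same orientation (for clusters inside an annotated ORF, the
containing gene, category ``internal``).  External clusters assign
unconditionally within 100 bp of the relevant ORF boundary; between 100 and
1000 bp, 30-bp windows slid base-by-base across the gap must all show
positive median mRNA coverage (TES clusters additionally must satisfy
5%-of-gene-median and 5x-gene-max window criteria, evidence that the gap is
continuously transcribed as part of the same mRNA).  UTR lengths are apex
to ORF-boundary distances in nucleotides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .clusters import SiteCluster
from .io import CoverageTrack, GeneModel

__all__ = ["GeneAssignment", "assign_tss", "assign_tes", "assign_all", "utr_length"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAssignment:
    """Link of one cluster to one gene.

    ``distance_to_feature`` is the signed distance from the cluster apex to
    the ORF start (TSS) or ORF end (TES): positive when the cluster is
    external to the ORF, 0 at the boundary.  ``utr_length`` equals that
    distance for external clusters and is None for internal ones.
    """

    cluster_id: str
    gene_id: str
    category: str  # upstream | internal | downstream
    distance_to_feature: int
    utr_length: Optional[int]


def _inside(gene: GeneModel, pos: int) -> bool:
    return gene.orf_start <= pos < gene.orf_end


def _tss_distance(gene: GeneModel, apex: int) -> int:
    """Distance from apex to the first base of the start codon (>0 upstream)."""
    return gene.orf_start - apex if gene.strand == "+" else apex - (gene.orf_end - 1)


def _tes_distance(gene: GeneModel, apex: int) -> int:
    """Distance from the ORF 3' boundary to the apex (>0 downstream)."""
    return apex - gene.orf_end if gene.strand == "+" else gene.orf_start - 1 - apex


def _antisense_overlap(cluster: SiteCluster, genes: Sequence[GeneModel]) -> bool:
    return any(
        g.contig == cluster.contig
        and g.strand != cluster.strand
        and _inside(g, cluster.apex)
        for g in genes
    )


def _pick_closest(
    cluster: SiteCluster,
    genes: Sequence[GeneModel],
    distance_fn,
) -> Optional[tuple[GeneModel, int]]:
    """Closest same-strand gene by the given apex distance; None if none apply.

    Internal candidates (apex inside the ORF) win immediately.  Ties between
    equidistant external genes break to the 5'-most gene start on the
    cluster strand.
    """
    candidates = [
        g
        for g in genes
        if g.contig == cluster.contig and g.strand == cluster.strand
    ]
    for g in candidates:
        if _inside(g, cluster.apex):
            return g, 0
    external = [(g, distance_fn(g, cluster.apex)) for g in candidates]
    external = [(g, d) for g, d in external if d >= 0]
    if not external:
        return None
    best_d = min(d for _, d in external)
    tied = [g for g, d in external if d == best_d]
    if len(tied) > 1:
        logger.info(
            "cluster %s equidistant to %d genes; 5'-most start wins",
            cluster.cluster_id,
            len(tied),
        )
        key = (
            (lambda g: g.orf_start)
            if cluster.strand == "+"
            else (lambda g: -g.orf_end)
        )
        tied = sorted(tied, key=key)
    return tied[0], best_d


def _window_medians_ok(
    coverage: CoverageTrack,
    contig: str,
    strand: str,
    lo: int,
    hi: int,
    window: int = 30,
) -> bool:
    """Every 30-bp window (step 1) over [lo, hi) has median coverage > 0."""
    vals = coverage.values(contig, lo, hi, strand)
    if len(vals) == 0:
        return False
    if len(vals) <= window:
        return float(np.median(vals)) > 0
    windows = np.lib.stride_tricks.sliding_window_view(vals, window)
    return bool(np.all(np.median(windows, axis=1) > 0))


def assign_tss(
    cluster: SiteCluster,
    genes: Sequence[GeneModel],
    rna_coverage: CoverageTrack,
    near_dist: int = 100,
    far_dist: int = 1000,
    window: int = 30,
) -> Optional[GeneAssignment]:
    """Assign a 5'-end cluster to its downstream gene, or return None.

    Rules, in order: apex within ``near_dist`` bp upstream of the start
    codon -> assigned; apex within ``far_dist`` bp and every 30-bp sliding
    window between apex and start codon has positive median mRNA coverage ->
    assigned; apex inside the ORF -> internal.  Clusters whose apex falls in
    an opposite-strand ORF are treated as antisense and left unassigned.
    """
    if _antisense_overlap(cluster, genes):
        return None
    picked = _pick_closest(cluster, genes, _tss_distance)
    if picked is None:
        return None
    gene, dist = picked
    if _inside(gene, cluster.apex):
        return GeneAssignment(cluster.cluster_id, gene.gene_id, "internal", 0, None)
    if dist <= near_dist:
        return GeneAssignment(cluster.cluster_id, gene.gene_id, "upstream", dist, dist)
    if dist <= far_dist:
        if gene.strand == "+":
            lo, hi = cluster.apex, gene.orf_start
        else:
            lo, hi = gene.orf_end, cluster.apex + 1
        if _window_medians_ok(
            rna_coverage, cluster.contig, cluster.strand, lo, hi, window
        ):
            return GeneAssignment(
                cluster.cluster_id, gene.gene_id, "upstream", dist, dist
            )
    return None


def assign_tes(
    cluster: SiteCluster,
    genes: Sequence[GeneModel],
    rna_coverage: CoverageTrack,
    near_dist: int = 100,
    far_dist: int = 1000,
    window: int = 30,
    median_frac: float = 0.05,
    max_ratio: float = 5.0,
) -> Optional[GeneAssignment]:
    """Assign a 3'-end cluster to its upstream gene, or return None.

    As :func:`assign_tss`, but in the 100-1000 bp band each 30-bp window
    between the ORF end and the cluster must additionally have median
    coverage >= ``median_frac`` x the gene-body median and max coverage <=
    ``max_ratio`` x the gene-body max.
    """
    if _antisense_overlap(cluster, genes):
        return None
    picked = _pick_closest(cluster, genes, _tes_distance)
    if picked is None:
        return None
    gene, dist = picked
    if _inside(gene, cluster.apex):
        return GeneAssignment(cluster.cluster_id, gene.gene_id, "internal", 0, None)
    if dist <= near_dist:
        return GeneAssignment(
            cluster.cluster_id, gene.gene_id, "downstream", dist, dist
        )
    if dist <= far_dist:
        if gene.strand == "+":
            lo, hi = gene.orf_end, cluster.apex + 1
        else:
            lo, hi = cluster.apex, gene.orf_start
        gene_vals = rna_coverage.values(
            gene.contig, gene.orf_start, gene.orf_end, gene.strand
        )
        gene_median = float(np.median(gene_vals)) if len(gene_vals) else 0.0
        gene_max = float(np.max(gene_vals)) if len(gene_vals) else 0.0
        vals = rna_coverage.values(cluster.contig, lo, hi, cluster.strand)
        if len(vals) == 0:
            return None
        n = len(vals)
        w = min(window, n)
        windows = np.lib.stride_tricks.sliding_window_view(vals, w)
        medians = np.median(windows, axis=1)
        maxima = np.max(windows, axis=1)
        ok = bool(
            np.all(medians > 0)
            and np.all(medians >= median_frac * gene_median)
            and np.all(maxima <= max_ratio * gene_max)
        )
        if ok:
            return GeneAssignment(
                cluster.cluster_id, gene.gene_id, "downstream", dist, dist
            )
    return None


def assign_all(
    clusters: Sequence[SiteCluster],
    genes: Sequence[GeneModel],
    rna_coverage: CoverageTrack,
    **kwargs,
) -> List[GeneAssignment]:
    """Assign every cluster by kind; unassignable clusters are dropped."""
    out: List[GeneAssignment] = []
    for c in clusters:
        fn = assign_tss if c.kind == "TSS" else assign_tes
        a = fn(c, genes, rna_coverage, **kwargs)
        if a is not None:
            out.append(a)
    return out


def utr_length(assignment: GeneAssignment) -> Optional[int]:
    """UTR length in nt for an external assignment (None for internal).

    5' UTR: apex to the first base of the start codon; 3' UTR: ORF 3'
    boundary to the apex.
    """
    if assignment.category == "internal":
        return None
    return assignment.utr_length
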