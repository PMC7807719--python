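"""Artifact removal for 5'- and 3'-end signal.

Two classes of artifact are handled:

* spurious 5'-end clusters — positions that still yield ligatable ends in a
  library prepared *without* the decapping step.  A cluster whose base-wise
  raw-count profile in the non-decapping control correlates with the
  reference sample (Spearman r > 0.5, p < 0.05 over the cluster +/- 5 bp)
  is flagged spurious and excluded from downstream analysis.

* internal-priming 3'-ends — apparent poly(A) sites created by the oligo-dT
  primer annealing to a genomic A-rich tract.  Any 3'-end site overlapping,
  or within 5 nt upstream of, a 20-mer window with <= 8 mismatches to
  poly(A) (read on the transcript strand) is removed *before* TES cluster
  calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats

from .clusters import SiteCluster
from .io import EndCountTrack, GenomeSequence

__all__ = [
    "PolyATract",
    "SpuriousCall",
    "flag_spurious_tss",
    "find_polya_tracts",
    "filter_internal_priming",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PolyATract:
    """A genomic homopolymer tract capable of internal oligo-dT priming.

    ``mismatches`` is the smallest number of mismatches over the 20-mer
    windows merged into this tract (a merged tract may exceed 20 bp).
    """

    contig: str
    strand: str
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class SpuriousCall:
    cluster_id: str
    spearman_r: float
    p_value: float
    spurious: bool


def flag_spurious_tss(
    cluster: SiteCluster,
    decapped: EndCountTrack,
    nondecapped: EndCountTrack,
    flank: int = 5,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
    contig_length: int | None = None,
) -> SpuriousCall:
    """Test one TSS cluster for correlated signal in the non-decapping control.

    Raw (not TPM) base-wise counts over ``[start - flank, end + flank)`` are
    rank-correlated between the two tracks.  A spurious verdict requires
    positive evidence: if either vector is constant the correlation is
    undefined and the cluster is kept.
    """
    start = cluster.start - flank
    end = cluster.end + flank
    if start < 0 or (contig_length is not None and end > contig_length):
        logger.warning(
            "cluster %s window truncated to contig bounds", cluster.cluster_id
        )
        start = max(start, 0)
        if contig_length is not None:
            end = min(end, contig_length)
    x = decapped.window_counts(cluster.contig, start, end)
    y = nondecapped.window_counts(cluster.contig, start, end)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpuriousCall(cluster.cluster_id, float("nan"), float("nan"), False)
    r, p = stats.spearmanr(x, y)
    if np.isnan(r):
        return SpuriousCall(cluster.cluster_id, float("nan"), float("nan"), False)
    spurious = bool(r > r_threshold and p < p_threshold)
    return SpuriousCall(cluster.cluster_id, float(r), float(p), spurious)


def _window_match_tracts(
    match: np.ndarray, contig: str, strand: str, motif_len: int, max_mismatch: int
) -> List[PolyATract]:
    """Merge qualifying sliding windows over a 0/1 match vector into tracts."""
    if len(match) < motif_len:
        return []
    kernel = np.ones(motif_len, dtype=int)
    matches_per_window = np.convolve(match, kernel, mode="valid")
    ok = np.flatnonzero(matches_per_window >= motif_len - max_mismatch)
    tracts: List[PolyATract] = []
    if len(ok) == 0:
        return tracts
    run_start = prev = ok[0]
    best = int(motif_len - matches_per_window[ok[0]])
    for w in ok[1:]:
        if w <= prev + motif_len:  # windows overlap or touch: same tract
            best = min(best, int(motif_len - matches_per_window[w]))
            prev = w
        else:
            tracts.append(
                PolyATract(contig, strand, int(run_start), int(prev) + motif_len, best)
            )
            run_start = prev = w
            best = int(motif_len - matches_per_window[w])
    tracts.append(
        PolyATract(contig, strand, int(run_start), int(prev) + motif_len, best)
    )
    return tracts


def find_polya_tracts(
    genome: GenomeSequence,
    motif_len: int = 20,
    max_mismatch: int = 8,
) -> List[PolyATract]:
    """Locate all degenerate poly(A) tracts on both strands of the genome.

    On the plus strand a tract is a window of ``motif_len`` reference bases
    with at least ``motif_len - max_mismatch`` A's; on the minus strand, T's
    (poly(A) as read on the transcript).  Overlapping qualifying windows
    merge into maximal tracts.
    """
    if motif_len <= 0:
        raise ValueError("motif_len must be > 0")
    tracts: List[PolyATract] = []
    for contig, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for strand, base in (("+", ord("A")), ("-", ord("T"))):
            match = (arr == base).astype(int)
            tracts.extend(
                _window_match_tracts(match, contig, strand, motif_len, max_mismatch)
            )
    return tracts


def filter_internal_priming(
    tes_track: EndCountTrack,
    tracts: Sequence[PolyATract],
    max_dist: int = 5,
) -> EndCountTrack:
    """Drop 3'-end sites attributable to internal priming on poly(A) tracts.

    A site at position p on the transcript strand is removed when a
    same-strand tract overlaps p, or when the tract begins within
    ``max_dist`` nt downstream of p (downstream in the direction of
    transcription).  Returns a new track; library size is recomputed so TES
    TPM normalization happens on the filtered library.
    """
    strand = tes_track.strand
    by_contig: Dict[str, List[PolyATract]] = {}
    for t in tracts:
        if t.strand == strand:
            by_contig.setdefault(t.contig, []).append(t)

    filtered = EndCountTrack(
        sample_id=tes_track.sample_id,
        timepoint=tes_track.timepoint,
        replicate=tes_track.replicate,
        strand=strand,
        counts={},
    )
    for contig, positions in tes_track.counts.items():
        ctracts = by_contig.get(contig, [])
        starts = np.array([t.start for t in ctracts])
        ends = np.array([t.end for t in ctracts])
        kept: Dict[int, int] = {}
        for pos, count in positions.items():
            if len(ctracts):
                overlap = np.any((starts <= pos) & (pos < ends))
                if strand == "+":
                    near = np.any((starts > pos) & (starts - pos <= max_dist))
                else:
                    near = np.any((ends - 1 < pos) & (pos - (ends - 1) <= max_dist))
                if overlap or near:
                    continue
            kept[pos] = count
        if kept:
            filtered.counts[contig] = kept
    filtered.library_size = filtered.total()
    return filtered
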