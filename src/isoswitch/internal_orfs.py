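"""Internal TSSs and the truncated ORFs they may encode.

A TSS cluster is *internal* when its apex lies inside an annotated ORF.
Internal clusters that are >= 2-fold upregulated during a transition pass
the relaxed cutoff; the stringent cutoff additionally requires the
internal cluster's TPM to reach one third of the gene's main (full-length)
TSS cluster at the same timepoint and the predicted downstream ORF to be
at least 300 nt.  ORF prediction scans the transcript-sense sequence from
the internal apex to the annotated stop codon in all three frames
(sense strand only) and reports the longest AUG..stop ORF; the internal
transcript's leader length is the distance from the apex to the first AUG
in frame with the annotated ORF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

from .clusters import SiteCluster
from .io import GeneModel, GenomeSequence

__all__ = [
    "PredictedOrf",
    "InternalTssCall",
    "classify_internal",
    "relaxed_filter",
    "stringent_filter",
    "predict_orf",
    "leader_length",
]

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
MIN_ORF_LEN = 300
FULL_LENGTH_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class PredictedOrf:
    """A candidate truncated ORF in transcript-forward orientation.

    ``start``/``end`` are genomic 0-based half-open; ``length`` counts
    nucleotides from the AUG through the stop codon.
    """

    contig: str
    strand: str
    start: int
    end: int
    length: int
    frame_offset: int  # nt offset of the AUG from the window 5' end


@dataclass
class InternalTssCall:
    cluster_id: str
    gene_id: str
    relaxed: bool
    stringent: bool
    fraction_of_full_length: Optional[float]
    predicted_orf: Optional[PredictedOrf]
    leader_length: Optional[int]


def classify_internal(cluster: SiteCluster, gene: GeneModel) -> bool:
    """Internal iff the apex lies in [orf_start, orf_end) on the gene strand."""
    return (
        cluster.contig == gene.contig
        and cluster.strand == gene.strand
        and gene.orf_start <= cluster.apex < gene.orf_end
    )


def relaxed_filter(diff_rows) -> bool:
    """Relaxed cutoff: significantly 2-fold up at >= 1 transition timepoint.

    ``diff_rows`` is an iterable of per-timepoint DE records (anything with
    ``log2fc`` and ``padj`` attributes or keys).
    """
    for row in diff_rows:
        if row is None:
            continue
        log2fc = row["log2fc"] if not hasattr(row, "log2fc") else row.log2fc
        padj = row["padj"] if not hasattr(row, "padj") else row.padj
        if padj is not None and padj == padj and log2fc >= 1.0 and padj < 0.05:
            return True
    return False


def stringent_filter(
    relaxed: bool,
    internal_tpm: float,
    full_length_tpm: Optional[float],
    predicted_orf: Optional[PredictedOrf],
    fraction: float = FULL_LENGTH_FRACTION,
    min_orf_len: int = MIN_ORF_LEN,
) -> bool:
    """Stringent cutoff: relaxed, plus expression at >= ``fraction`` of the
    main full-length cluster at the same timepoint, plus a predicted ORF of
    >= ``min_orf_len`` nt.  An undefined main TPM fails the cutoff."""
    if not relaxed:
        return False
    if full_length_tpm is None:
        logger.info("stringent filter: main (full-length) TPM undefined")
        return False
    if predicted_orf is None or predicted_orf.length < min_orf_len:
        return False
    return internal_tpm >= fraction * full_length_tpm


def _transcript_window(
    genome: GenomeSequence, apex: int, gene: GeneModel
) -> str:
    """Sense-strand sequence from the internal apex to the annotated stop."""
    if gene.strand == "+":
        return genome.fetch(gene.contig, apex, gene.orf_end, "+")
    return genome.fetch(gene.contig, gene.orf_start, apex + 1, "-")


def predict_orf(
    genome: GenomeSequence,
    internal_tss_apex: int,
    gene: GeneModel,
    min_len: int = MIN_ORF_LEN,
) -> Optional[PredictedOrf]:
    """Longest AUG..stop ORF downstream of an internal TSS, sense strand only.

    All three frames of the window from the apex to the gene's annotated
    stop are scanned (the candidate ORF may be out of frame with the
    annotated one); candidates extending past the annotated ORF end are not
    considered.  Returns None when no ORF reaches ``min_len`` nt.
    """
    window = _transcript_window(genome, internal_tss_apex, gene)
    if len(window) < min_len:
        return None
    best: Optional[tuple] = None  # (length, start_offset, end_offset)
    for frame in range(3):
        i = frame
        open_start: Optional[int] = None
        while i + 3 <= len(window):
            codon = window[i : i + 3]
            if open_start is None and codon == "ATG":
                open_start = i
            elif open_start is not None and codon in STOP_CODONS:
                length = i + 3 - open_start
                if length >= min_len and (best is None or length > best[0]):
                    best = (length, open_start, i + 3)
                open_start = None
            i += 3
    if best is None:
        return None
    length, s_off, e_off = best
    if gene.strand == "+":
        g_start = internal_tss_apex + s_off
        g_end = internal_tss_apex + e_off
    else:
        g_end = internal_tss_apex + 1 - s_off
        g_start = internal_tss_apex + 1 - e_off
    return PredictedOrf(
        contig=gene.contig,
        strand=gene.strand,
        start=g_start,
        end=g_end,
        length=length,
        frame_offset=s_off,
    )


def leader_length(
    genome: GenomeSequence, internal_tss_apex: int, gene: GeneModel
) -> Optional[int]:
    """Distance (nt) from the apex to the first downstream AUG in frame with
    the annotated ORF; None when no in-frame AUG remains."""
    window = _transcript_window(genome, internal_tss_apex, gene)
    # transcript-coordinate offset of the apex from the annotated start codon
    if gene.strand == "+":
        apex_offset = internal_tss_apex - gene.orf_start
    else:
        apex_offset = (gene.orf_end - 1) - internal_tss_apex
    phase = (-apex_offset) % 3  # first in-frame codon boundary in the window
    i = phase
    while i + 3 <= len(window):
        if window[i : i + 3] == "ATG":
            return i
        i += 3
    return None
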