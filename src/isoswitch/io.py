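"""Readers/writers for the text formats the pipeline touches, and the shared
coordinate conventions.

All internal coordinates are 0-based half-open.  bedGraph files are already
0-based half-open; GFF3 (1-based inclusive) is converted on read and write.
A transcript 5'-end ("TSS") site is the 5'-most templated base of a read, a
3'-end ("TES") site the 3'-most; the strand of the track decides which
genomic direction counts as downstream.

Count tracks are stored as sparse ``position -> count`` maps because
single-nucleotide end data is overwhelmingly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "EndCountTrack",
    "CoverageTrack",
    "read_bedgraph",
    "write_bedgraph",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "write_results",
    "read_results",
]

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Uppercase nucleotide sequences keyed by contig name."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if len(seq) == 0:
                raise ValueError(f"empty sequence for contig {name!r}")

    def __getitem__(self, contig: str) -> str:
        return self.sequences[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of ``[start, end)`` read in transcript sense."""
        seq = self.sequences[contig][max(start, 0) : end]
        return revcomp(seq) if strand == "-" else seq


@dataclass(frozen=True)
class GeneModel:
    """A single-ORF gene: the annotated coding interval on one strand.

    ``orf_start``/``orf_end`` delimit the ORF from the first base of the
    start codon through the last base of the stop codon, 0-based half-open.
    """

    gene_id: str
    contig: str
    strand: str
    orf_start: int
    orf_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.orf_start < self.orf_end:
            raise ValueError(
                f"gene {self.gene_id}: orf_start ({self.orf_start}) must be "
                f"< orf_end ({self.orf_end})"
            )

    @property
    def tss_anchor(self) -> int:
        """Genomic position of the first base of the start codon."""
        return self.orf_start if self.strand == "+" else self.orf_end - 1

    @property
    def tes_anchor(self) -> int:
        """Genomic position of the last base of the stop codon."""
        return self.orf_end - 1 if self.strand == "+" else self.orf_start


@dataclass
class EndCountTrack:
    """Strand-specific per-base counts of transcript 5'- or 3'-ends.

    ``library_size`` is the total number of counted ends for the sample
    over both strands; by default it is the total of this track alone and
    is updated by :func:`pair_library_size` once the mate strand is known.
    """

    sample_id: str
    timepoint: str
    replicate: int
    strand: str
    counts: Dict[str, Dict[int, int]] = field(default_factory=dict)
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.library_size == 0:
            self.library_size = self.total()

    def total(self) -> int:
        return int(sum(sum(c.values()) for c in self.counts.values()))

    def add(self, contig: str, position: int, count: int) -> None:
        if count < 0:
            raise ValueError(f"negative count {count} at {contig}:{position}")
        if count == 0:
            return
        self.counts.setdefault(contig, {})[position] = (
            self.counts.get(contig, {}).get(position, 0) + count
        )

    def window_counts(self, contig: str, start: int, end: int) -> np.ndarray:
        """Dense vector of counts over ``[start, end)``."""
        out = np.zeros(end - start, dtype=float)
        positions = self.counts.get(contig, {})
        for pos, c in positions.items():
            if start <= pos < end:
                out[pos - start] = c
        return out


def pair_library_size(plus: EndCountTrack, minus: EndCountTrack) -> int:
    """Set both tracks' library size to the summed ends of the strand pair."""
    total = plus.total() + minus.total()
    plus.library_size = total
    minus.library_size = total
    return total


@dataclass
class CoverageTrack:
    """Dense per-base, strand-specific read coverage (mRNA-seq-like)."""

    plus: Dict[str, np.ndarray]
    minus: Dict[str, np.ndarray]

    def values(self, contig: str, start: int, end: int, strand: str) -> np.ndarray:
        arr = (self.plus if strand == "+" else self.minus).get(contig)
        if arr is None:
            return np.zeros(max(end - start, 0))
        start = max(start, 0)
        end = min(end, len(arr))
        if end <= start:
            return np.zeros(0)
        return arr[start:end]


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path: str | Path,
    strand: str,
    sample_id: str = "",
    timepoint: str = "",
    replicate: int = 0,
) -> EndCountTrack:
    """Read a 4-column bedGraph file into a sparse end-count track.

    Every covered base of each record is materialized; values must be
    non-negative integers (counts of sequenced ends).
    """
    track = EndCountTrack(
        sample_id=sample_id or Path(path).stem,
        timepoint=timepoint,
        replicate=replicate,
        strand=strand,
    )
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(fields)}"
                )
            contig, start_s, end_s, value_s = fields
            try:
                start, end = int(start_s), int(end_s)
                value = float(value_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if value < 0:
                raise ValueError(f"{path}: line {lineno}: negative value {value}")
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            ivalue = int(round(value))
            for pos in range(start, end):
                track.add(contig, pos, ivalue)
    track.library_size = track.total()
    return track


def write_bedgraph(track: EndCountTrack, path: str | Path) -> None:
    """Write a track as canonically sorted bedGraph with run-length merging."""
    with open(path, "w") as fh:
        for contig in sorted(track.counts):
            items = sorted(track.counts[contig].items())
            run_start = None
            prev_pos = prev_val = None
            for pos, val in items:
                if val == 0:
                    continue
                if run_start is not None and pos == prev_pos + 1 and val == prev_val:
                    prev_pos = pos
                    continue
                if run_start is not None:
                    fh.write(f"{contig}\t{run_start}\t{prev_pos + 1}\t{prev_val}\n")
                run_start, prev_pos, prev_val = pos, pos, val
            if run_start is not None:
                fh.write(f"{contig}\t{run_start}\t{prev_pos + 1}\t{prev_val}\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> List[GeneModel]:
    """Read gene models from GFF3 (gene/CDS features, 1-based inclusive).

    Coordinates convert to 0-based half-open; strand is preserved verbatim
    (no flipping for minus-strand genes).
    """
    genes: List[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns")
            contig, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype not in ("gene", "CDS"):
                continue
            if ftype == "CDS":
                # single-ORF annotations: the gene line already carries the
                # full coding interval
                continue
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(f"{path}: line {lineno}: end < start")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("gene_id")
            if not gene_id:
                raise ValueError(f"{path}: line {lineno}: missing ID attribute")
            if gene_id in seen:
                raise ValueError(f"{path}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig=contig,
                    strand=strand,
                    orf_start=start - 1,
                    orf_end=end,
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tisoswitch\tgene\t{g.orf_start + 1}\t{g.orf_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA into a :class:`GenomeSequence`; sequences are uppercased."""
    sequences: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate contig {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty record {record.id!r}")
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"{path}: no FASTA records found")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# result tables


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> List[Path]:
    """Write result DataFrames as TSV files with a header row, one per table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
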