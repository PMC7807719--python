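"""File-based dataset interchange for the command-line interface.

A simulated (or externally prepared) dataset lives in one directory:
FASTA genome, GFF3 annotation, one bedGraph per sample / strand / end kind
(suffix convention ``.plus.bedgraph`` / ``.minus.bedgraph``), a
non-decapping control pair, run-length-encoded mRNA coverage per
timepoint, a per-gene occupancy-change TSV, truth tables when simulated,
and a ``manifest.yaml`` tying everything together.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml

from .io import (
    CoverageTrack,
    EndCountTrack,
    read_bedgraph,
    read_fasta,
    read_gff3,
    write_bedgraph,
    write_fasta,
    write_gff3,
)
from .synthetic import CohortParams, CohortSpec, SimulatedDataset

__all__ = ["write_dataset", "load_dataset"]

_STRAND_SUFFIX = {"+": "plus", "-": "minus"}
_SUFFIX_STRAND = {v: k for k, v in _STRAND_SUFFIX.items()}


def _coverage_to_frame(cov: CoverageTrack) -> pd.DataFrame:
    rows = []
    for strand, arrays in (("+", cov.plus), ("-", cov.minus)):
        for contig, arr in arrays.items():
            vals = np.asarray(arr)
            if not vals.any():
                continue
            change = np.flatnonzero(np.diff(vals) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for s, e in zip(starts, ends):
                v = float(vals[s])
                if v != 0:
                    rows.append((contig, strand, int(s), int(e), v))
    return pd.DataFrame(
        rows, columns=["contig", "strand", "start", "end", "value"]
    )


def _frame_to_coverage(
    df: pd.DataFrame, lengths: Dict[str, int]
) -> CoverageTrack:
    plus = {c: np.zeros(n, dtype=np.float32) for c, n in lengths.items()}
    minus = {c: np.zeros(n, dtype=np.float32) for c, n in lengths.items()}
    for row in df.itertuples(index=False):
        arr = plus[row.contig] if row.strand == "+" else minus[row.contig]
        arr[row.start : row.end] = row.value
    return CoverageTrack(plus=plus, minus=minus)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> Path:
    """Serialize a dataset as plain-text files plus a manifest."""
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    spec = dataset.spec
    write_fasta(spec.genome, out / "genome.fasta")
    write_gff3(spec.genes, out / "annotation.gff3")

    track_entries: List[dict] = []
    for kind, store in (("tss", dataset.tss), ("tes", dataset.tes)):
        for (sid, strand), track in sorted(store.items()):
            name = f"{kind}_{sid}.{_STRAND_SUFFIX[strand]}.bedgraph"
            write_bedgraph(track, out / "tracks" / name)
            track_entries.append(
                {
                    "kind": kind,
                    "sample_id": sid,
                    "timepoint": track.timepoint,
                    "replicate": track.replicate,
                    "strand": strand,
                    "path": f"tracks/{name}",
                    "library_size": int(track.library_size),
                }
            )
    for strand, track in sorted(dataset.nondecapped.items()):
        name = f"nondecapped.{_STRAND_SUFFIX[strand]}.bedgraph"
        write_bedgraph(track, out / "tracks" / name)
        track_entries.append(
            {
                "kind": "nondecapped",
                "sample_id": "nondecapped",
                "timepoint": spec.params.reference,
                "replicate": 1,
                "strand": strand,
                "path": f"tracks/{name}",
                "library_size": int(track.library_size),
            }
        )

    for tp, cov in dataset.coverage.items():
        _coverage_to_frame(cov).to_csv(
            out / f"coverage_{tp}.tsv", sep="\t", index=False
        )
    pd.DataFrame(
        sorted(dataset.occupancy.items()), columns=["gene_id", "occupancy_change"]
    ).to_csv(out / "occupancy.tsv", sep="\t", index=False)
    if spec.truth:
        spec.truth_frame().to_csv(out / "truth_genes.tsv", sep="\t", index=False)

    manifest = {
        "genome": "genome.fasta",
        "annotation": "annotation.gff3",
        "occupancy": "occupancy.tsv",
        "timepoints": list(spec.params.timepoints),
        "n_replicates": spec.params.n_replicates,
        "samples": [
            {"sample_id": sid, "timepoint": tp, "replicate": r}
            for sid, tp, r in dataset.samples
        ],
        "coverage": {
            tp: f"coverage_{tp}.tsv" for tp in dataset.coverage
        },
        "tracks": track_entries,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out / "manifest.yaml"


def load_dataset(manifest_path: str | Path) -> SimulatedDataset:
    """Load a dataset directory back into memory.

    The returned object carries empty truth/plan tables (truth is only
    meaningful for freshly simulated data and is read separately when
    scoring against it).
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)

    genome = read_fasta(base / manifest["genome"])
    genes = read_gff3(base / manifest["annotation"])
    timepoints = tuple(manifest["timepoints"])
    params = CohortParams(
        timepoints=timepoints, n_replicates=int(manifest["n_replicates"])
    )
    samples = [
        (s["sample_id"], s["timepoint"], int(s["replicate"]))
        for s in manifest["samples"]
    ]

    tss: Dict[Tuple[str, str], EndCountTrack] = {}
    tes: Dict[Tuple[str, str], EndCountTrack] = {}
    nondecapped: Dict[str, EndCountTrack] = {}
    for entry in manifest["tracks"]:
        track = read_bedgraph(
            base / entry["path"],
            entry["strand"],
            sample_id=entry["sample_id"],
            timepoint=entry["timepoint"],
            replicate=int(entry["replicate"]),
        )
        track.library_size = int(entry["library_size"])
        if entry["kind"] == "tss":
            tss[(entry["sample_id"], entry["strand"])] = track
        elif entry["kind"] == "tes":
            tes[(entry["sample_id"], entry["strand"])] = track
        else:
            nondecapped[entry["strand"]] = track

    lengths = {c: len(s) for c, s in genome.sequences.items()}
    coverage = {
        tp: _frame_to_coverage(
            pd.read_csv(base / path, sep="\t", float_precision="round_trip"),
            lengths,
        )
        for tp, path in manifest["coverage"].items()
    }
    occ_df = pd.read_csv(
        base / manifest["occupancy"], sep="\t", float_precision="round_trip"
    )
    occupancy = dict(zip(occ_df["gene_id"], occ_df["occupancy_change"]))

    spec = CohortSpec(
        genome=genome,
        genes=genes,
        plans=[],
        truth={},
        params=params,
        priming_tracts=[],
        spurious_plan_ids=[],
        priming_plan_ids=[],
    )
    return SimulatedDataset(
        spec=spec,
        samples=samples,
        tss=tss,
        tes=tes,
        nondecapped=nondecapped,
        coverage=coverage,
        occupancy=occupancy,
    )
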