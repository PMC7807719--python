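"""Synthetic genomes and end-count tracks with planted ground truth.

The generator emulates the statistical structure of strand-specific 5'/3'
end-sequencing of a synchronized yeast time course: narrow clusters of
single-nucleotide end positions around promoter and terminator anchors
(geometric positional decay), TPM-scale cluster strengths, two-fold-or-more
transition-specific induction of alternative TSSs, tandem TSS pairs at
controlled spacing (a proximal < 80 bp and a distal >= 80 bp regime),
negative-binomial replicate noise, genomic poly(A) tracts with adjacent
internal-priming 3'-end artifacts, and spurious non-decapped promoter
signal mirrored into a non-decapping control library.

Gene classes planted in the default cohort:

* ``repressed``    — upstream alternative TSS strongly induced, main TSS
                     down >= 2-fold (a switching/repression event);
* ``coactivated``  — both alternative and main induced >= 2-fold;
* ``neutral``      — alternative induced, main unchanged;
* ``stable``       — background genes, nothing changes;
* ``internal_switch`` — ORF-internal TSS dominant before the transition,
                     promoter TSS induced above it during the transition;
* ``internal_induced`` — promoter TSS dominant, ORF-internal TSS induced
                     >= 2-fold to at least one third of the main level (a
                     candidate truncated-protein isoform).

Every dataset carries truth tables sufficient to score each downstream
stage.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import CoverageTrack, EndCountTrack, GeneModel, GenomeSequence, revcomp

__all__ = [
    "CohortParams",
    "ClusterPlan",
    "GeneTruth",
    "CohortSpec",
    "SimulatedDataset",
    "generate_genome_and_annotation",
    "build_cohort_spec",
    "simulate_tracks",
    "simulate_mutant_pair",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
STOPS = ("TAA", "TAG", "TGA")
NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]

DEFAULT_TIMEPOINTS = ("t0", "t1", "t2", "t3")  # t0 = pre-transition reference


@dataclass
class CohortParams:
    """Default study conditions for the synthetic cohort."""

    n_repressed: int = 100
    n_coactivated: int = 100
    n_neutral: int = 100
    n_stable: int = 300
    n_internal_switch: int = 30
    n_internal_induced: int = 30
    n_spurious: int = 20
    n_priming: int = 50
    n_filler: int = 200
    timepoints: Tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    library_size: int = 2_000_000
    dispersion: float = 0.05
    decay_p: float = 0.5
    decay_width: int = 8
    main_tpm_range: Tuple[float, float] = (25.0, 80.0)
    alt_tpm_range: Tuple[float, float] = (2.0, 6.0)

    @property
    def reference(self) -> str:
        return self.timepoints[0]

    @property
    def n_genes(self) -> int:
        return (
            self.n_repressed
            + self.n_coactivated
            + self.n_neutral
            + self.n_stable
            + self.n_internal_switch
            + self.n_internal_induced
        )


@dataclass
class ClusterPlan:
    """One planted cluster: an anchor plus a per-timepoint expected TPM."""

    plan_id: str
    gene_id: Optional[str]
    kind: str  # TSS | TES
    role: str  # main | alternative | internal | tes | filler | spurious | priming
    contig: str
    strand: str
    anchor: int
    expected_tpm: Dict[str, float]
    decay_dir: int  # +1 / -1 genomic direction of the positional decay
    in_nondecapped: bool = False
    spread: Optional[List[int]] = None  # explicit offsets overriding decay


@dataclass
class GeneTruth:
    gene_id: str
    label: str
    main_tss_anchor: Optional[int]
    alt_tss_anchor: Optional[int]
    internal_anchor: Optional[int]
    tes_anchor: int
    pair_distance: Optional[int]
    main_fold: float
    alt_fold: float
    occupancy_change: float
    switch: bool = False  # planted Fig-3c-style promoter switching event
    response: Optional[str] = None  # planted main response: down|up|unchanged
    internal_relaxed: bool = False
    internal_stringent: bool = False


@dataclass
class CohortSpec:
    genome: GenomeSequence
    genes: List[GeneModel]
    plans: List[ClusterPlan]
    truth: Dict[str, GeneTruth]
    params: CohortParams
    priming_tracts: List[Tuple[str, str, int, int]]  # contig, strand, start, end
    spurious_plan_ids: List[str]
    priming_plan_ids: List[str]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.truth.values()])


@dataclass
class SimulatedDataset:
    spec: CohortSpec
    samples: List[Tuple[str, str, int]]  # (sample_id, timepoint, replicate)
    tss: Dict[Tuple[str, str], EndCountTrack]  # (sample_id, strand) -> track
    tes: Dict[Tuple[str, str], EndCountTrack]
    nondecapped: Dict[str, EndCountTrack]  # strand -> control track
    coverage: Dict[str, CoverageTrack]  # timepoint -> mRNA-like coverage
    occupancy: Dict[str, float]


# ---------------------------------------------------------------------------
# genome and annotation


def _random_cds(rng: np.random.Generator, orf_len: int) -> str:
    """A start codon, stop-free random codons, and a stop codon."""
    n_body = orf_len // 3 - 2
    body = "".join(
        NONSTOP_CODONS[i] for i in rng.integers(0, len(NONSTOP_CODONS), n_body)
    )
    stop = STOPS[int(rng.integers(3))]
    return "ATG" + body + stop


def generate_genome_and_annotation(
    n_genes: int,
    seed: int = 0,
    orf_codons: Tuple[int, int] = (300, 500),
    intergenic: int = 1800,
    margin: int = 1500,
) -> Tuple[GenomeSequence, List[GeneModel], np.random.Generator]:
    """Random genome with non-overlapping single-ORF genes on both strands.

    ORF lengths are multiples of 3 with proper start/stop codons (reverse
    complemented for minus-strand genes); intergenic spacing comfortably
    exceeds 1.2 kb so default assignment windows are unambiguous.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes: List[GeneModel] = []
    cursor = margin
    placements = []
    for i in range(n_genes):
        orf_len = 3 * int(rng.integers(orf_codons[0], orf_codons[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        placements.append((f"gene{i + 1:04d}", cursor, cursor + orf_len, strand))
        cursor += orf_len + intergenic
    total_len = cursor + margin
    arr = BASES[rng.integers(0, 4, total_len)]
    seq = bytearray(arr.tobytes())
    for gene_id, start, end, strand in placements:
        cds = _random_cds(rng, end - start)
        if strand == "-":
            cds = revcomp(cds)
        seq[start:end] = cds.encode()
        genes.append(GeneModel(gene_id, "chr1", strand, start, end))
    genome = GenomeSequence({"chr1": seq.decode()})
    return genome, genes, rng


# ---------------------------------------------------------------------------
# cohort architecture


def _tss_anchor(gene: GeneModel, offset: int) -> int:
    """Genomic position ``offset`` nt upstream of the start codon."""
    return gene.orf_start - offset if gene.strand == "+" else gene.orf_end - 1 + offset


def _tes_anchor_pos(gene: GeneModel, offset: int) -> int:
    """Genomic position ``offset`` nt downstream of the ORF 3' boundary."""
    return gene.orf_end + offset if gene.strand == "+" else gene.orf_start - 1 - offset


def _internal_pos(gene: GeneModel, offset: int) -> int:
    """Genomic position ``offset`` nt into the ORF from the start codon."""
    return gene.orf_start + offset if gene.strand == "+" else gene.orf_end - 1 - offset


def _downstream_dir(gene: GeneModel) -> int:
    return 1 if gene.strand == "+" else -1


def build_cohort_spec(
    params: CohortParams = CohortParams(), seed: int = 0
) -> CohortSpec:
    """Plant the full cohort: genome, gene classes, clusters, artifacts.

    Main TSSs sit a median ~75 nt upstream of the AUG; alternative TSSs sit
    further upstream at tandem spacings drawn from a proximal (< 80 bp) and
    a distal (>= 80 bp) regime.  Induced alternatives rise 8-20x across the
    transition; repressed mains fall 3-7x, co-activated mains rise ~4x.
    Nucleosome occupancy between the tandem TSSs rises preferentially at
    repressed genes (the planted negative occupancy effect).
    """
    genome, genes, rng = generate_genome_and_annotation(params.n_genes, seed)
    labels = (
        ["repressed"] * params.n_repressed
        + ["coactivated"] * params.n_coactivated
        + ["neutral"] * params.n_neutral
        + ["stable"] * params.n_stable
        + ["internal_switch"] * params.n_internal_switch
        + ["internal_induced"] * params.n_internal_induced
    )
    labels = [labels[i] for i in rng.permutation(len(labels))]
    tps = params.timepoints
    ref = params.reference
    trans_tps = tps[1:]

    plans: List[ClusterPlan] = []
    truth: Dict[str, GeneTruth] = {}
    atg_plants: List[Tuple[GeneModel, int]] = []

    def ramp(start: float, end_: float) -> Dict[str, float]:
        """Expected TPM trajectory: reference value ramping to the plateau."""
        traj = {ref: start}
        for j, tp in enumerate(trans_tps):
            frac = (j + 1) / len(trans_tps)
            # reach the plateau by the second transition timepoint
            level = start + (end_ - start) * min(1.0, 2 * frac)
            traj[tp] = level
        return traj

    for gene, label in zip(genes, labels):
        gid = gene.gene_id
        main_off = int(np.clip(rng.normal(75, 15), 25, 140))
        # tandem spacing keeps a margin above the 20-bp aggregation distance
        # so genuinely distinct promoters stay distinct after merging
        spacing = (
            int(rng.integers(40, 80))
            if rng.random() < 0.4
            else int(rng.integers(90, 300))
        )
        alt_off = main_off + spacing
        tes_off = int(np.clip(rng.normal(100, 20), 40, 200))
        main_ref = float(rng.uniform(*params.main_tpm_range))
        alt_ref = float(
            rng.uniform(
                params.alt_tpm_range[0],
                min(params.alt_tpm_range[1], main_ref / 10.0),
            )
        )
        alt_fold = float(rng.uniform(8, 20))
        down = _downstream_dir(gene)

        occ = float(rng.normal(0.0, 0.4))
        main_fold = 1.0
        internal_anchor = None
        if label == "repressed":
            # distal upstream transcription represses more deeply
            if spacing >= 80:
                main_fold = float(rng.uniform(0.12, 0.25))  # 4-8x down
            else:
                main_fold = float(rng.uniform(0.18, 0.33))  # 3-5x down
            occ = float(rng.normal(0.8, 0.4))
        elif label == "coactivated":
            main_fold = float(rng.uniform(3.0, 6.0))

        if label in ("internal_switch", "internal_induced"):
            orf_len = gene.orf_end - gene.orf_start
            int_off = 3 * int(rng.integers(60, min(150, orf_len // 3 - 110)))
            internal_anchor = _internal_pos(gene, int_off)
            # guarantee a translatable truncated ORF: in-frame AUG 15 nt
            # downstream of the internal apex
            atg_plants.append((gene, int_off + 15))
        if label == "internal_switch":
            # internal TSS dominant before the transition, promoter TSS
            # induced above it during the transition
            int_ref = float(rng.uniform(20, 35))
            int_end = int_ref * float(rng.uniform(0.3, 0.45))
            prom_ref = float(rng.uniform(1.5, 3.0))
            prom_end = max(prom_ref * alt_fold * 2, 2.0 * int_end)
            plans.append(
                ClusterPlan(
                    f"{gid}:internal",
                    gid,
                    "TSS",
                    "internal",
                    gene.contig,
                    gene.strand,
                    internal_anchor,
                    ramp(int_ref, int_end),
                    down,
                )
            )
            plans.append(
                ClusterPlan(
                    f"{gid}:promoter",
                    gid,
                    "TSS",
                    "alternative",
                    gene.contig,
                    gene.strand,
                    _tss_anchor(gene, main_off),
                    ramp(prom_ref, prom_end),
                    down,
                )
            )
            truth[gid] = GeneTruth(
                gid,
                label,
                internal_anchor,
                _tss_anchor(gene, main_off),
                internal_anchor,
                _tes_anchor_pos(gene, tes_off),
                None,
                1.0,
                prom_end / prom_ref,
                occ,
                switch=True,  # the promoter overtakes the internal dominant
            )
        elif label == "internal_induced":
            # promoter dominant throughout; internal cluster rises to at
            # least 40% of the (constant) main level
            int_ref = alt_ref
            int_end = max(float(rng.uniform(0.4, 0.8)) * main_ref, 4 * int_ref)
            plans.append(
                ClusterPlan(
                    f"{gid}:main",
                    gid,
                    "TSS",
                    "main",
                    gene.contig,
                    gene.strand,
                    _tss_anchor(gene, main_off),
                    ramp(main_ref, main_ref),
                    down,
                )
            )
            plans.append(
                ClusterPlan(
                    f"{gid}:internal",
                    gid,
                    "TSS",
                    "internal",
                    gene.contig,
                    gene.strand,
                    internal_anchor,
                    ramp(int_ref, int_end),
                    down,
                )
            )
            truth[gid] = GeneTruth(
                gid,
                label,
                _tss_anchor(gene, main_off),
                None,
                internal_anchor,
                _tes_anchor_pos(gene, tes_off),
                None,
                1.0,
                int_end / int_ref,
                occ,
                internal_relaxed=True,
                internal_stringent=True,
            )
        else:
            plans.append(
                ClusterPlan(
                    f"{gid}:main",
                    gid,
                    "TSS",
                    "main",
                    gene.contig,
                    gene.strand,
                    _tss_anchor(gene, main_off),
                    ramp(main_ref, main_ref * main_fold),
                    down,
                )
            )
            if label == "repressed":
                # the alternative overtakes the repressed main
                alt_end = max(alt_ref * alt_fold, 1.5 * main_ref * main_fold)
            elif label == "coactivated":
                # clearly induced but never dominant over the rising main
                alt_end = float(
                    np.clip(alt_ref * alt_fold, 4 * alt_ref, 0.4 * main_ref * main_fold)
                )
            elif label == "neutral":
                alt_end = float(
                    np.clip(alt_ref * alt_fold, 4 * alt_ref, 0.4 * main_ref)
                )
            else:  # stable
                alt_end = alt_ref
            plans.append(
                ClusterPlan(
                    f"{gid}:alt",
                    gid,
                    "TSS",
                    "alternative",
                    gene.contig,
                    gene.strand,
                    _tss_anchor(gene, alt_off),
                    ramp(alt_ref, alt_end),
                    down,
                )
            )
            truth[gid] = GeneTruth(
                gid,
                label,
                _tss_anchor(gene, main_off),
                _tss_anchor(gene, alt_off),
                None,
                _tes_anchor_pos(gene, tes_off),
                spacing,
                main_fold,
                alt_end / alt_ref,
                occ,
                switch=(label == "repressed"),
                response={
                    "repressed": "down",
                    "coactivated": "up",
                    "neutral": "unchanged",
                }.get(label),
            )
        # one terminator cluster tracking total gene output
        tes_traj = {
            tp: sum(
                p.expected_tpm[tp] for p in plans if p.gene_id == gid and p.kind == "TSS"
            )
            for tp in tps
        }
        plans.append(
            ClusterPlan(
                f"{gid}:tes",
                gid,
                "TES",
                "tes",
                gene.contig,
                gene.strand,
                _tes_anchor_pos(gene, tes_off),
                tes_traj,
                -down,  # decay back into the gene body
            )
        )

    # spurious non-decapped promoters inside stable gene bodies
    stable_genes = [g for g in genes if truth[g.gene_id].label == "stable"]
    spurious_ids: List[str] = []
    for g in stable_genes[: params.n_spurious]:
        orf_len = g.orf_end - g.orf_start
        pos = _internal_pos(g, orf_len // 2)
        pid = f"{g.gene_id}:spurious"
        plans.append(
            ClusterPlan(
                pid,
                g.gene_id,
                "TSS",
                "spurious",
                g.contig,
                g.strand,
                pos,
                {tp: 15.0 for tp in tps},
                _downstream_dir(g),
                in_nondecapped=True,
            )
        )
        spurious_ids.append(pid)

    # internal-priming artifacts: an A20 tract in the ORF with 3' ends
    # planted 1-5 nt upstream of it on the transcript strand
    seq = bytearray(genome.sequences["chr1"].encode())
    for gene, sense_off in atg_plants:
        if gene.strand == "+":
            p = gene.orf_start + sense_off
            seq[p : p + 3] = b"ATG"
        else:
            p = gene.orf_end - sense_off
            seq[p - 3 : p] = b"CAT"
    priming_ids: List[str] = []
    priming_tracts: List[Tuple[str, str, int, int]] = []
    priming_genes = [g for g in stable_genes[params.n_spurious :]][: params.n_priming]
    for g in priming_genes:
        orf_len = g.orf_end - g.orf_start
        sense_off = (orf_len // 2) + (orf_len // 4)
        if g.strand == "+":
            ts = g.orf_start + sense_off
            seq[ts : ts + 20] = b"A" * 20
            offsets = [ts - j for j in range(1, 6)]
        else:
            te = g.orf_end - sense_off
            seq[te - 20 : te] = b"T" * 20
            ts, = (te - 20,)
            offsets = [te - 1 + j for j in range(1, 6)]
            ts = te - 20
        priming_tracts.append((g.contig, g.strand, ts, ts + 20))
        pid = f"{g.gene_id}:priming"
        plans.append(
            ClusterPlan(
                pid,
                g.gene_id,
                "TES",
                "priming",
                g.contig,
                g.strand,
                offsets[0],
                {tp: 6.0 for tp in tps},
                0,
                spread=offsets,
            )
        )
        priming_ids.append(pid)

    genome = GenomeSequence({"chr1": seq.decode()})
    genome = _scrub_accidental_tracts(genome, genes, plans, priming_tracts)

    # background "housekeeping" loci on a separate contig absorb the rest of
    # each library so planted TPMs are on their nominal scale
    bg_len = params.n_filler * 250 + 500
    bg_rng = np.random.default_rng(seed + 104729)
    bg_seq = BASES[bg_rng.integers(0, 4, bg_len)].tobytes().decode()
    genome.sequences["chrBg"] = bg_seq
    planted_tpm = {
        kind: {
            tp: sum(p.expected_tpm[tp] for p in plans if p.kind == kind)
            for tp in tps
        }
        for kind in ("TSS", "TES")
    }
    n_each = params.n_filler // 2
    for i in range(params.n_filler):
        kind = "TSS" if i < n_each else "TES"
        share = {
            tp: max(1e6 - planted_tpm[kind][tp], 0.0) / n_each for tp in tps
        }
        plans.append(
            ClusterPlan(
                f"bg{i:04d}",
                None,
                kind,
                "filler",
                "chrBg",
                "+",
                250 * i + 100,
                share,
                1,
            )
        )

    return CohortSpec(
        genome=genome,
        genes=genes,
        plans=plans,
        truth=truth,
        params=params,
        priming_tracts=priming_tracts,
        spurious_plan_ids=spurious_ids,
        priming_plan_ids=priming_ids,
    )


def _scrub_accidental_tracts(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    plans: Sequence[ClusterPlan],
    planted: Sequence[Tuple[str, str, int, int]],
) -> GenomeSequence:
    """Break chance poly(A)/(T) tracts near true TES clusters.

    A random genome occasionally contains a degenerate A-rich window that
    would catch a genuine terminator in the internal-priming filter; every
    such window near a true TES anchor is disrupted by writing C at
    alternating positions (sparing planted tracts and annotated stop
    codons).  Codons gaining a C can never become stop codons, so the gene
    models stay valid.
    """
    from .filters import find_polya_tracts

    protected = set()
    for g in genes:
        if g.strand == "+":
            protected.update(range(g.orf_end - 3, g.orf_end))
        else:
            protected.update(range(g.orf_start, g.orf_start + 3))
    planted_zones = [
        (strand, start, end) for _, strand, start, end in planted
    ]
    true_tes = [
        (p.strand, p.anchor)
        for p in plans
        if p.kind == "TES" and p.role == "tes"
    ]
    seq = bytearray(genome.sequences["chr1"].encode())
    for _round in range(3):
        tracts = [
            t for t in find_polya_tracts(genome) if t.contig == "chr1"
        ]
        dirty = False
        for t in tracts:
            if any(
                s == t.strand and t.start < e + 25 and ts < t.end + 25
                for s, ts, e in planted_zones
            ):
                continue
            near = False
            for strand, anchor in true_tes:
                if strand != t.strand:
                    continue
                # the called TES cluster can span ~20 nt around the anchor
                zone_lo, zone_hi = anchor - 20, anchor + 20
                if t.start <= zone_hi and zone_lo < t.end:
                    near = True
                elif strand == "+" and 0 < t.start - zone_hi <= 6:
                    near = True
                elif strand == "-" and 0 < zone_lo - (t.end - 1) <= 6:
                    near = True
                if near:
                    break
            if not near:
                continue
            dirty = True
            for pos in range(t.start, t.end, 2):
                if pos not in protected:
                    seq[pos] = ord("C")
        genome = GenomeSequence(
            {**genome.sequences, "chr1": seq.decode()}
        )
        if not dirty:
            break
    return genome


# ---------------------------------------------------------------------------
# track simulation


def _decay_weights(p: float, width: int) -> np.ndarray:
    w = p * (1 - p) ** np.arange(width)
    return w / w.sum()


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Counts with mean m and variance m + dispersion * m^2 (Gamma-Poisson)."""
    means = np.asarray(means, dtype=float)
    if dispersion <= 0:
        return rng.poisson(means)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * means)
    return rng.poisson(lam)


def _plan_positions(plan: ClusterPlan, weights: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    if plan.spread is not None:
        pos = np.array(plan.spread)
        w = _decay_weights(0.5, len(pos))
        return pos, w
    pos = plan.anchor + plan.decay_dir * np.arange(len(weights))
    return pos, weights


def simulate_tracks(
    spec: CohortSpec,
    seed: int = 0,
    n_replicates: Optional[int] = None,
    library_size: Optional[int] = None,
    dispersion: Optional[float] = None,
) -> SimulatedDataset:
    """Draw replicate end-count tracks for every planted cluster.

    For each cluster and timepoint the expected count is TPM x library /
    1e6, spread over ~8 nt with a geometric positional profile.  Replicate
    noise is Gamma-Poisson with a per-(gene, sample) gamma factor shared by
    all clusters of a gene, so each position is marginally negative
    binomial (variance m + dispersion * m^2) while biological fluctuation
    moves a gene's promoters together — as in real biological replicates,
    where within-gene usage proportions are far more stable than absolute
    levels.  Spurious clusters are mirrored into a non-decapping control
    track, and per-timepoint mRNA-like coverage consistent with the
    isoform spans is emitted for the assignment windows.
    """
    params = spec.params
    n_rep = n_replicates or params.n_replicates
    lib = library_size or params.library_size
    disp = params.dispersion if dispersion is None else dispersion
    rng = np.random.default_rng(seed)
    weights = _decay_weights(params.decay_p, params.decay_width)

    samples = [
        (f"{tp}_rep{r}", tp, r)
        for tp in params.timepoints
        for r in range(1, n_rep + 1)
    ]
    tss: Dict[Tuple[str, str], EndCountTrack] = {}
    tes: Dict[Tuple[str, str], EndCountTrack] = {}
    for sid, tp, r in samples:
        for strand in "+-":
            tss[(sid, strand)] = EndCountTrack(sid, tp, r, strand, {}, 1)
            tes[(sid, strand)] = EndCountTrack(sid, tp, r, strand, {}, 1)
    nondecapped = {
        strand: EndCountTrack("nondecapped", params.reference, 1, strand, {}, 1)
        for strand in "+-"
    }

    # gene-level biological factors, shared by all clusters of one gene
    factor_keys = sorted({p.gene_id or p.plan_id for p in spec.plans})
    shape = 1.0 / disp if disp > 0 else None
    factors: Dict[Tuple[str, str], float] = {}
    for key in factor_keys:
        for sid, _tp, _r in samples + [("nondecapped", params.reference, 1)]:
            factors[(key, sid)] = (
                float(rng.gamma(shape, disp)) if shape is not None else 1.0
            )

    for plan in spec.plans:
        positions, w = _plan_positions(plan, weights)
        store = tss if plan.kind == "TSS" else tes
        key = plan.gene_id or plan.plan_id
        for sid, tp, r in samples:
            mean_total = plan.expected_tpm[tp] * lib / 1e6
            counts = rng.poisson(factors[(key, sid)] * mean_total * w)
            track = store[(sid, plan.strand)]
            for pos, c in zip(positions, counts):
                if c > 0:
                    track.add(plan.contig, int(pos), int(c))
        if plan.in_nondecapped:
            mean_total = plan.expected_tpm[params.reference] * lib / 1e6
            counts = rng.poisson(
                factors[(key, "nondecapped")] * mean_total * w
            )
            track = nondecapped[plan.strand]
            for pos, c in zip(positions, counts):
                if c > 0:
                    track.add(plan.contig, int(pos), int(c))

    # library sizes: total ends of the strand pair per sample
    for store in (tss, tes):
        for sid, tp, r in samples:
            total = store[(sid, "+")].total() + store[(sid, "-")].total()
            store[(sid, "+")].library_size = total
            store[(sid, "-")].library_size = total
    for strand in "+-":
        nondecapped[strand].library_size = max(nondecapped[strand].total(), 1)

    coverage = _build_coverage(spec)
    occupancy = {gid: t.occupancy_change for gid, t in spec.truth.items()}
    return SimulatedDataset(
        spec=spec,
        samples=samples,
        tss=tss,
        tes=tes,
        nondecapped=nondecapped,
        coverage=coverage,
        occupancy=occupancy,
    )


def _build_coverage(spec: CohortSpec) -> Dict[str, CoverageTrack]:
    """Per-timepoint mRNA-like coverage: each isoform span (its TSS anchor
    to the gene's TES anchor) contributes its expected TPM."""
    lengths = {c: len(s) for c, s in spec.genome.sequences.items()}
    out: Dict[str, CoverageTrack] = {}
    tes_anchor = {
        p.gene_id: p.anchor
        for p in spec.plans
        if p.kind == "TES" and p.role == "tes"
    }
    for tp in spec.params.timepoints:
        plus = {c: np.zeros(n, dtype=np.float32) for c, n in lengths.items()}
        minus = {c: np.zeros(n, dtype=np.float32) for c, n in lengths.items()}
        for p in spec.plans:
            if p.kind != "TSS" or p.gene_id is None or p.role == "spurious":
                continue
            t_anchor = tes_anchor.get(p.gene_id)
            if t_anchor is None:
                continue
            lo, hi = sorted((p.anchor, t_anchor))
            arr = plus[p.contig] if p.strand == "+" else minus[p.contig]
            arr[lo : hi + 1] += p.expected_tpm[tp]
        out[tp] = CoverageTrack(plus=plus, minus=minus)
    return out


def simulate_determinant_records(
    n: int = 164,
    coefs: Tuple[float, float, float] = (-0.4, -0.3, -0.2),
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Determinant records from a known linear model, for regression checks.

    main_log2fc = c_alt * alt_level + c_dist * log2(distance) + c_occ *
    occupancy + noise, with tandem distances drawn from the proximal/distal
    mixture.  Returns (records, generating_r2) where generating_r2 is the
    empirical fraction of response variance explained by the linear part.
    """
    from .determinants import DeterminantRecord

    rng = np.random.default_rng(seed)
    alt = rng.normal(3.0, 1.2, n)
    dist = np.where(
        rng.random(n) < 0.4,
        rng.uniform(20, 80, n),
        rng.uniform(80, 300, n),
    )
    log2_dist = np.log2(dist)
    occ = rng.normal(0.0, 1.0, n)
    linear = coefs[0] * alt + coefs[1] * log2_dist + coefs[2] * occ
    y = linear + rng.normal(0.0, noise_sd, n)
    r2 = float(np.var(linear) / np.var(y))
    records = [
        DeterminantRecord(
            gene_id=f"g{i:04d}",
            transition="T",
            pair_distance=int(round(dist[i])),
            alt_level=float(alt[i]),
            main_prior_level=float(rng.uniform(1, 50)),
            main_log2fc=float(y[i]),
            occupancy_change=float(occ[i]),
        )
        for i in range(n)
    ]
    return records, r2


def simulate_mutant_pair(
    spec: CohortSpec,
    effect_size: float = 3.0,
    derepressed_fraction: float = 0.2,
    stage: Optional[str] = None,
    seed: int = 0,
    n_replicates: Optional[int] = None,
) -> Tuple[SimulatedDataset, SimulatedDataset, pd.DataFrame]:
    """Control and mutant track sets at one stage, plus a truth table.

    The stage defaults to the last transition timepoint (where upstream
    repression is active in control cells).  De-repressed genes — a subset
    of the planted ``repressed`` genes of size
    ceil(derepressed_fraction x n_genes) — get their main-TSS expectation
    multiplied by ``effect_size`` in the mutant only; all other clusters
    are statistically exchangeable between genotypes.
    """
    params = spec.params
    stage = stage or params.timepoints[-1]
    rng = np.random.default_rng(seed)
    repressed = sorted(
        gid for gid, t in spec.truth.items() if t.label == "repressed"
    )
    n_derepressed = int(np.ceil(derepressed_fraction * len(spec.truth)))
    if effect_size == 1.0:
        n_derepressed = 0
    if n_derepressed > len(repressed):
        raise ValueError(
            f"need {n_derepressed} repressed genes, cohort has {len(repressed)}"
        )
    chosen = sorted(
        np.array(repressed)[rng.permutation(len(repressed))[:n_derepressed]]
    )
    chosen_set = set(chosen)

    def stage_spec(mutant: bool) -> CohortSpec:
        plans = []
        for p in spec.plans:
            tpm = p.expected_tpm[stage]
            if mutant and p.role == "main" and p.gene_id in chosen_set:
                tpm = tpm * effect_size
            plans.append(
                ClusterPlan(
                    p.plan_id,
                    p.gene_id,
                    p.kind,
                    p.role,
                    p.contig,
                    p.strand,
                    p.anchor,
                    {stage: tpm},
                    p.decay_dir,
                    p.in_nondecapped,
                    p.spread,
                )
            )
        import dataclasses

        sub_params = dataclasses.replace(params, timepoints=(stage,))
        return CohortSpec(
            genome=spec.genome,
            genes=spec.genes,
            plans=plans,
            truth=spec.truth,
            params=sub_params,
            priming_tracts=spec.priming_tracts,
            spurious_plan_ids=spec.spurious_plan_ids,
            priming_plan_ids=spec.priming_plan_ids,
        )

    control = simulate_tracks(
        stage_spec(False), seed=int(rng.integers(2**31 - 1)), n_replicates=n_replicates
    )
    mutant = simulate_tracks(
        stage_spec(True), seed=int(rng.integers(2**31 - 1)), n_replicates=n_replicates
    )
    truth = pd.DataFrame(
        {
            "gene_id": sorted(spec.truth),
            "derepressed": [g in chosen_set for g in sorted(spec.truth)],
        }
    )
    return control, mutant, truth
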