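"""Internal-TSS calls, truncated-ORF prediction, leader lengths."""

import numpy as np
import pytest

from isoswitch.clusters import SiteCluster
from isoswitch.internal_orfs import (
    classify_internal,
    leader_length,
    predict_orf,
    relaxed_filter,
    stringent_filter,
)
from isoswitch.io import GeneModel, GenomeSequence, revcomp
from isoswitch.synthetic import NONSTOP_CODONS


def cluster(apex, strand="+"):
    return SiteCluster("c", "chr1", strand, apex, apex + 1, apex=apex)


def orf_scan_oracle(window, min_len):
    """Plain 3-frame scan for the longest AUG..stop ORF."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for frame in range(3):
        starts = []
        for i in range(frame, len(window) - 2, 3):
            codon = window[i : i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in stops:
                for s in starts:
                    length = i + 3 - s
                    if length >= min_len and (best is None or length > best[1] - best[0]):
                        best = (s, i + 3)
                starts = []
    return best


def random_gene(rng, strand, n_codons=350):
    """A gene with stop-free body on a random background."""
    body = "".join(
        NONSTOP_CODONS[i] for i in rng.integers(0, len(NONSTOP_CODONS), n_codons)
    )
    cds = "ATG" + body + "TAA"
    if strand == "-":
        cds = revcomp(cds)
    pad5 = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    pad3 = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    seq = pad5 + cds + pad3
    gene = GeneModel("g", "chr1", strand, 300, 300 + len(cds))
    return GenomeSequence({"chr1": seq}), gene


class TestClassifyInternal:
    def test_boundary_conventions(self):
        gene = GeneModel("g", "chr1", "+", 100, 400)
        assert classify_internal(cluster(100), gene)  # orf_start inclusive
        assert not classify_internal(cluster(400), gene)  # orf_end exclusive
        assert not classify_internal(cluster(99), gene)

    def test_strand_must_match(self):
        gene = GeneModel("g", "chr1", "-", 100, 400)
        assert not classify_internal(cluster(200, "+"), gene)
        assert classify_internal(cluster(200, "-"), gene)

    def test_cohort_internal_flags_match_truth(
        self, small_cohort, small_cohort_result
    ):
        spec, _ = small_cohort
        assigns = small_cohort_result["tables"]["assignments"]
        internal = assigns[
            (assigns.category == "internal") & (assigns.kind == "TSS")
        ]
        planted = {
            t.internal_anchor
            for t in spec.truth.values()
            if t.internal_anchor is not None
        }
        clusters = {
            c.cluster_id: c for c in small_cohort_result["kept_tss"]
        }
        recovered = {
            clusters[cid].apex
            for cid in internal.cluster_id
            if clusters[cid].apex in planted
        }
        assert len(recovered) / len(planted) >= 0.9


class TestRelaxedStringent:
    def row(self, fc, q):
        return {"log2fc": fc, "padj": q}

    def test_relaxed_threshold(self):
        assert relaxed_filter([self.row(1.3, 0.01)])
        assert not relaxed_filter([self.row(0.85, 0.01)])
        assert not relaxed_filter([self.row(1.3, 0.2)])
        assert relaxed_filter([None, self.row(1.3, 0.01)])

    def test_stringent_fraction_and_orf_floor(self):
        orf450 = predict_stub(450)
        assert stringent_filter(True, 10.0, 24.0, orf450)
        assert not stringent_filter(True, 7.0, 24.0, orf450)
        assert not stringent_filter(True, 10.0, 24.0, predict_stub(297))
        assert not stringent_filter(True, 10.0, None, orf450)
        assert not stringent_filter(False, 10.0, 3.0, orf450)

    def test_stringent_subset_of_relaxed(self, small_cohort_result):
        ic = small_cohort_result["tables"]["internal_calls"]
        assert not (ic.stringent & ~ic.relaxed).any()


def predict_stub(length):
    from isoswitch.internal_orfs import PredictedOrf

    return PredictedOrf("chr1", "+", 0, length, length, 0)


class TestPredictOrf:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_planted_orf_recovered(self, strand):
        rng = np.random.default_rng(0)
        genome, gene = random_gene(rng, strand)
        # internal apex 120 codons into the ORF, in frame
        offset = 360
        apex = (
            gene.orf_start + offset
            if strand == "+"
            else gene.orf_end - 1 - offset
        )
        orf = predict_orf(genome, apex, gene)
        window = (
            genome.fetch("chr1", apex, gene.orf_end, "+")
            if strand == "+"
            else genome.fetch("chr1", gene.orf_start, apex + 1, "-")
        )
        oracle = orf_scan_oracle(window, 300)
        assert orf is not None and oracle is not None
        assert orf.length == oracle[1] - oracle[0]

    def test_no_atg_returns_none(self):
        seq = "C" * 400
        gene = GeneModel("g", "chr1", "+", 0, 399)
        assert predict_orf(GenomeSequence({"chr1": seq}), 10, gene) is None

    def test_window_shorter_than_min_len(self):
        rng = np.random.default_rng(1)
        genome, gene = random_gene(rng, "+")
        apex = gene.orf_end - 100
        assert predict_orf(genome, apex, gene) is None

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_three_frame_oracle(self, seed, strand):
        """Random apexes on random genes, both strands, vs the plain scan."""
        rng = np.random.default_rng(seed)
        genome, gene = random_gene(rng, strand, n_codons=int(rng.integers(150, 400)))
        for _ in range(25):
            off = int(rng.integers(0, gene.orf_end - gene.orf_start - 10))
            apex = (
                gene.orf_start + off if strand == "+" else gene.orf_end - 1 - off
            )
            got = predict_orf(genome, apex, gene)
            window = (
                genome.fetch("chr1", apex, gene.orf_end, "+")
                if strand == "+"
                else genome.fetch("chr1", gene.orf_start, apex + 1, "-")
            )
            oracle = orf_scan_oracle(window, 300)
            if oracle is None:
                assert got is None
            else:
                assert got is not None
                assert got.length == oracle[1] - oracle[0]
                assert got.frame_offset == oracle[0]

    def test_orf_bounded_by_annotated_stop(self):
        rng = np.random.default_rng(3)
        genome, gene = random_gene(rng, "+")
        orf = predict_orf(genome, gene.orf_start, gene)
        assert orf is not None
        assert orf.end <= gene.orf_end


class TestLeaderLength:
    def test_apex_on_in_frame_aug(self):
        rng = np.random.default_rng(4)
        genome, gene = random_gene(rng, "+")
        assert leader_length(genome, gene.orf_start, gene) == 0

    def test_apex_two_nt_before_in_frame_aug(self):
        seq = "CC" + "ATG" + "GGGCCC" * 60 + "TAA" + "CC"
        gene = GeneModel("g", "chr1", "+", 2, 2 + 3 + 360 + 3)
        genome = GenomeSequence({"chr1": seq})
        assert leader_length(genome, 0, gene) == 2

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_frame_walk_oracle(self, strand, seed):
        rng = np.random.default_rng(100 + seed)
        genome, gene = random_gene(rng, strand)
        for _ in range(20):
            off = int(rng.integers(0, gene.orf_end - gene.orf_start - 3))
            apex = (
                gene.orf_start + off if strand == "+" else gene.orf_end - 1 - off
            )
            got = leader_length(genome, apex, gene)
            window = (
                genome.fetch("chr1", apex, gene.orf_end, "+")
                if strand == "+"
                else genome.fetch("chr1", gene.orf_start, apex + 1, "-")
            )
            phase = (-off) % 3
            expected = None
            for i in range(phase, len(window) - 2, 3):
                if window[i : i + 3] == "ATG":
                    expected = i
                    break
            assert got == expected

    def test_strand_reflection_symmetry(self):
        """Mirrored constructs give identical leader lengths."""
        rng = np.random.default_rng(9)
        genome_p, gene_p = random_gene(rng, "+")
        seq_m = revcomp(genome_p.sequences["chr1"])
        n = len(seq_m)
        gene_m = GeneModel(
            "g", "chr1", "-", n - gene_p.orf_end, n - gene_p.orf_start
        )
        genome_m = GenomeSequence({"chr1": seq_m})
        for off in (0, 3, 33, 150):
            apex_p = gene_p.orf_start + off
            apex_m = gene_m.orf_end - 1 - off
            assert leader_length(genome_p, apex_p, gene_p) == leader_length(
                genome_m, apex_m, gene_m
            )
            orf_p = predict_orf(genome_p, apex_p, gene_p)
            orf_m = predict_orf(genome_m, apex_m, gene_m)
            assert (orf_p is None) == (orf_m is None)
            if orf_p is not None:
                assert orf_p.length == orf_m.length
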