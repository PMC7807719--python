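"""Spurious-TSS and internal-priming artifact filters."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from isoswitch.clusters import SiteCluster
from isoswitch.filters import (
    PolyATract,
    filter_internal_priming,
    find_polya_tracts,
    flag_spurious_tss,
)
from isoswitch.io import GenomeSequence

from conftest import make_track


def cluster(start, end, strand="+"):
    return SiteCluster("c1", "chr1", strand, start, end, apex=start)


def spearman_oracle(x, y):
    """Rank (average ranks for ties) then Pearson; t-approximation p."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    if sxx == 0 or syy == 0:
        return None, None
    r = sxy / math.sqrt(sxx * syy)
    if abs(r) >= 1:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, p


class TestSpuriousFilter:
    def test_identical_profiles_flagged(self):
        counts = {100: 30, 101: 14, 102: 7, 103: 3, 104: 2, 106: 1}
        decapped = make_track(counts)
        nondecapped = make_track(counts)
        call = flag_spurious_tss(cluster(100, 107), decapped, nondecapped)
        assert call.spearman_r == pytest.approx(1.0)
        assert call.spurious

    def test_all_zero_control_kept(self):
        decapped = make_track({100: 30, 101: 14, 102: 7})
        nondecapped = make_track({})
        call = flag_spurious_tss(cluster(100, 103), decapped, nondecapped)
        assert not call.spurious
        assert math.isnan(call.spearman_r)

    def test_window_truncated_at_contig_start(self):
        decapped = make_track({0: 5, 1: 3, 2: 2})
        nondecapped = make_track({0: 4, 1: 3, 2: 1})
        call = flag_spurious_tss(
            cluster(0, 3), decapped, nondecapped, contig_length=2000
        )
        assert isinstance(call.spurious, bool)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rank_then_pearson_oracle(self, seed):
        """Verdicts match a brute-force rank/Pearson oracle, 200 windows."""
        rng = np.random.default_rng(seed)
        for _ in range(200):
            width = int(rng.integers(4, 15))
            start = 50
            x = rng.poisson(rng.uniform(0, 8), width + 10)
            y = rng.poisson(rng.uniform(0, 8), width + 10)
            dec = make_track({start - 5 + i: int(v) for i, v in enumerate(x) if v})
            ndc = make_track({start - 5 + i: int(v) for i, v in enumerate(y) if v})
            call = flag_spurious_tss(cluster(start, start + width), dec, ndc)
            xo = [float(v) for v in x[: width + 10]]
            yo = [float(v) for v in y[: width + 10]]
            r, p = spearman_oracle(xo, yo)
            if r is None:
                assert not call.spurious
            else:
                expected = r > 0.5 and p < 0.05
                assert call.spurious == expected
                assert call.spearman_r == pytest.approx(r, abs=1e-9)


class TestPolyATracts:
    def test_exact_motif(self):
        rng = np.random.default_rng(3)
        seq = "".join("CGT"[i] for i in rng.integers(0, 3, 200))
        seq = seq[:90] + "A" * 20 + seq[110:]
        tracts = [
            t for t in find_polya_tracts(GenomeSequence({"c": seq})) if t.strand == "+"
        ]
        assert any(t.start <= 90 and t.end >= 110 and t.mismatches == 0 for t in tracts)

    def test_nine_mismatches_not_reported(self):
        window = "A" * 11 + "C" * 9  # 9 non-A bases
        seq = "CGCGCGCGCG" + window + "CGCGCGCGCG"
        assert (
            find_polya_tracts(GenomeSequence({"c": seq}), max_mismatch=8) == []
        )

    def test_minus_strand_reads_t_runs(self):
        seq = "GCGC" + "T" * 20 + "GCGC"
        tracts = find_polya_tracts(GenomeSequence({"c": seq}))
        assert [t.strand for t in tracts] == ["-"]

    def test_bad_motif_len(self):
        with pytest.raises(ValueError):
            find_polya_tracts(GenomeSequence({"c": "ACGT"}), motif_len=0)

    def test_matches_sliding_window_brute_force(self):
        """Reported windows equal a per-window mismatch count on 10 kb."""
        rng = np.random.default_rng(42)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        genome = GenomeSequence({"c": seq})
        got = find_polya_tracts(genome)
        for strand, base in (("+", "A"), ("-", "T")):
            qualifying = set()
            for i in range(len(seq) - 19):
                if sum(1 for b in seq[i : i + 20] if b == base) >= 12:
                    qualifying.update(range(i, i + 20))
            covered = set()
            for t in got:
                if t.strand == strand:
                    covered.update(range(t.start, t.end))
            assert covered == qualifying


class TestPrimingFilter:
    def tract(self, start, strand="+"):
        return PolyATract("chr1", strand, start, start + 20, 0)

    def test_close_downstream_removed_far_kept(self):
        track = make_track({100: 9})
        assert filter_internal_priming(track, [self.tract(103)]).counts == {}
        kept = filter_internal_priming(track, [self.tract(107)])
        assert kept.counts == {"chr1": {100: 9}}

    def test_overlapping_removed(self):
        track = make_track({110: 4})
        assert filter_internal_priming(track, [self.tract(103)]).counts == {}

    def test_minus_strand_downstream_is_leftward(self):
        track = make_track({100: 9}, strand="-")
        # tract ending at 97 (last base 96): gap 4 -> removed
        assert (
            filter_internal_priming(track, [PolyATract("chr1", "-", 77, 97, 0)]).counts
            == {}
        )
        # tract on the transcript's upstream side -> kept
        kept = filter_internal_priming(track, [PolyATract("chr1", "-", 103, 123, 0)])
        assert kept.counts == {"chr1": {100: 9}}

    def test_monotone_in_tracts(self):
        rng = np.random.default_rng(5)
        track = make_track(
            {int(p): 1 for p in rng.choice(1000, 80, replace=False)}
        )
        tracts = [self.tract(int(s)) for s in rng.choice(1000, 10, replace=False)]
        kept_few = filter_internal_priming(track, tracts[:4]).counts.get("chr1", {})
        kept_all = filter_internal_priming(track, tracts).counts.get("chr1", {})
        assert set(kept_all) <= set(kept_few)

    def test_library_size_recomputed(self):
        track = make_track({100: 9, 500: 6})
        out = filter_internal_priming(track, [self.tract(103)])
        assert out.library_size == 6


def test_planted_artifacts_all_removed_no_true_tes_lost(small_cohort):
    """On the simulated cohort the priming filter removes every planted
    artifact position and no genuine terminator position."""
    spec, dataset = small_cohort
    tracts = find_polya_tracts(spec.genome)
    artifact_plans = {p.plan_id: p for p in spec.plans if p.role == "priming"}
    true_tes = [p for p in spec.plans if p.role == "tes"]
    for strand in "+-":
        track = dataset.tes[("t0_rep1", strand)]
        filtered = filter_internal_priming(track, tracts)
        kept = filtered.counts.get("chr1", {})
        for plan in artifact_plans.values():
            if plan.strand != strand:
                continue
            for pos in plan.spread:
                assert pos not in kept, "planted priming artifact survived"
        for plan in true_tes:
            if plan.strand != strand:
                continue
            before = track.counts.get("chr1", {})
            for off in range(8):
                pos = plan.anchor - plan.decay_dir * 0 + (plan.decay_dir * off)
                if pos in before:
                    assert pos in kept, "true TES position removed"
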