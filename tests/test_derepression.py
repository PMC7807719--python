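"""Cluster mapping across genotypes, CMH testing, de-repression calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable

from isoswitch.clusters import SiteCluster
from isoswitch.derepression import (
    ContingencyStack,
    call_derepression,
    cmh_test,
    map_clusters,
    relative_main_usage,
)


def sc(cid, start, end, strand="+"):
    return SiteCluster(cid, "chr1", strand, start, end, apex=start)


def stack(tables, gene="g"):
    st = ContingencyStack(gene)
    for (mc, mm), (ac, am) in tables:
        st.add_stratum(mc, mm, ac, am)
    return st


class TestMapClusters:
    def test_identical_intervals_map(self):
        m = map_clusters([sc("m1", 100, 120)], [sc("c1", 100, 120)])
        assert m == {"m1": "c1"}

    def test_disjoint_is_mutant_only(self):
        m = map_clusters([sc("m1", 100, 120)], [sc("c1", 300, 320)])
        assert m == {"m1": None}

    def test_one_bp_overlap_suffices(self):
        m = map_clusters([sc("m1", 100, 120)], [sc("c1", 119, 140)])
        assert m == {"m1": "c1"}

    def test_strand_mismatch_never_maps(self):
        m = map_clusters([sc("m1", 100, 120, "+")], [sc("c1", 100, 120, "-")])
        assert m == {"m1": None}

    def test_max_overlap_wins(self):
        controls = [sc("small", 100, 105), sc("big", 104, 140)]
        m = map_clusters([sc("m1", 100, 130)], controls)
        assert m == {"m1": "big"}

    def test_mapping_accuracy_on_perturbed_sets(self):
        """Jittered copies of control clusters map back >= 99%."""
        rng = np.random.default_rng(0)
        controls = [
            sc(f"c{i}", int(p), int(p) + 12)
            for i, p in enumerate(rng.choice(100_000, 300, replace=False) * 3)
        ]
        mutants = [
            sc(f"m{i}", c.start + int(rng.integers(-4, 5)), c.end + int(rng.integers(-4, 5)))
            for i, c in enumerate(controls)
        ]
        m = map_clusters(mutants, controls)
        correct = sum(
            1 for i in range(len(controls)) if m[f"m{i}"] == f"c{i}"
        )
        assert correct / len(controls) >= 0.99


class TestRelativeMainUsage:
    def test_ratio(self):
        assert relative_main_usage(10, [10, 12, 18]) == pytest.approx(0.25)

    def test_sole_cluster(self):
        assert relative_main_usage(5, [5]) == 1.0

    def test_zero_total_undefined(self):
        assert relative_main_usage(0, [0, 0]) is None

    def test_library_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            tpms = rng.uniform(0.1, 50, 5)
            k = rng.uniform(0.01, 100)
            assert relative_main_usage(tpms[0], tpms) == pytest.approx(
                relative_main_usage(k * tpms[0], k * tpms)
            )


class TestCmh:
    def test_textbook_formula_on_identical_strata(self):
        """Three identical strata vs the hand-evaluated formula."""
        st = stack([((10, 30), (90, 70))] * 3)
        statistic, p = cmh_test(st)
        # per stratum: a=10, E=row0*col0/n, V=r0*r1*c0*c1/(n^2 (n-1))
        a, e = 10.0, 40.0 * 100.0 / 200.0
        v = 40.0 * 160.0 * 100.0 * 100.0 / (200.0**2 * 199.0)
        expected = (abs(3 * (a - e)) - 0.5) ** 2 / (3 * v)
        assert statistic == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(float(sps.chi2.sf(expected, 1)), rel=1e-12)

    def test_identical_proportions_null(self):
        st = stack([((20, 40), (60, 120))] * 3)
        statistic, p = cmh_test(st)
        # only the continuity term remains: statistic ~ 0.25 / sum(V)
        assert statistic == pytest.approx(0.0, abs=0.01)
        assert p > 0.9
        statistic_nc, p_nc = cmh_test(st, continuity=False)
        assert statistic_nc == pytest.approx(0.0, abs=1e-12)
        assert p_nc == pytest.approx(1.0)

    def test_single_stratum_equals_corrected_chi2(self):
        """One stratum: CMH equals Yates' chi-square scaled by (N-1)/N.

        Both subtract 1/2 from the same |a - E|; the variance denominators
        differ exactly by the factor N/(N-1).
        """
        tab = [((12, 28), (34, 21))]
        statistic, _p = cmh_test(stack(tab))
        arr = np.array([[12, 28], [34, 21]], dtype=float)
        chi2 = sps.chi2_contingency(arr, correction=True).statistic
        n = arr.sum()
        assert statistic == pytest.approx(chi2 * (n - 1) / n, rel=1e-12)

    def test_degenerate_strata_dropped(self):
        st = stack([((0, 0), (0, 0)), ((10, 30), (90, 70))])
        statistic, p = cmh_test(st)
        assert statistic is not None
        st_all = stack([((0, 0), (0, 0))])
        assert cmh_test(st_all) == (None, None)

    def test_column_swap_leaves_statistic(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            tables = [
                (
                    (int(rng.integers(1, 80)), int(rng.integers(1, 80))),
                    (int(rng.integers(1, 80)), int(rng.integers(1, 80))),
                )
                for _ in range(3)
            ]
            swapped = [((mm, mc), (am, ac)) for (mc, mm), (ac, am) in tables]
            s1, _ = cmh_test(stack(tables))
            s2, _ = cmh_test(stack(swapped))
            assert s1 == pytest.approx(s2, rel=1e-12)

    @pytest.mark.parametrize("continuity", [True, False])
    def test_matches_reference_implementation(self, continuity):
        """1,000 random 2x2x3 stacks vs statsmodels' StratifiedTable."""
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(1000):
            tables = [
                rng.integers(1, 120, size=(2, 2)).astype(float) for _ in range(3)
            ]
            st = ContingencyStack("g", list(tables))
            statistic, p = cmh_test(st, continuity=continuity)
            ref = StratifiedTable(
                [t.copy() for t in tables]
            ).test_null_odds(correction=continuity)
            worst = max(worst, abs(p - float(ref.pvalue)))
            assert statistic == pytest.approx(float(ref.statistic), abs=1e-8)
        assert worst < 1e-6


class TestCallDerepression:
    def events(self, down_genes):
        return pd.DataFrame(
            {
                "gene_id": down_genes,
                "main_response": ["down"] * len(down_genes),
            }
        )

    def test_conjunction_of_conditions(self):
        stacks = {
            # strong usage shift toward main in the mutant
            "gA": stack([((10, 60), (90, 40))] * 3, "gA"),
            # shift away from main: not increased relative expression
            "gB": stack([((60, 10), (40, 90))] * 3, "gB"),
            # null gene
            "gC": stack([((30, 30), (70, 70))] * 3, "gC"),
        }
        res = {
            r.gene_id: r
            for r in call_derepression(stacks, self.events(["gA", "gB"]))
        }
        assert res["gA"].increased_relative_expression and res["gA"].derepressed
        assert not res["gB"].increased_relative_expression
        assert not res["gB"].derepressed
        assert not res["gC"].derepressed

    def test_derepressed_requires_control_repression(self):
        stacks = {"gA": stack([((10, 60), (90, 40))] * 3, "gA")}
        res = call_derepression(stacks, self.events([]))[0]
        assert res.increased_relative_expression and not res.derepressed

    def test_subset_invariant(self, small_cohort):
        """derepressed genes are always a subset of increased-usage genes."""
        from isoswitch import usage as usg
        from isoswitch.pipeline import run_cohort_analysis, run_derepression_analysis
        from isoswitch.synthetic import simulate_mutant_pair

        spec, dataset = small_cohort
        res = run_cohort_analysis(dataset)
        kept = {c.cluster_id: c for c in res["kept_tss"]}
        intervals = {}
        for gid, gcs in res["clusters_by_gene"].items():
            mid = usg.define_main(gcs, res["config"])
            if mid:
                c = kept[mid]
                intervals[gid] = (c.start, c.end, c.strand)
        control, mutant, _truth = simulate_mutant_pair(
            spec, effect_size=3.0, derepressed_fraction=0.08, seed=21
        )
        df = run_derepression_analysis(
            control, mutant, intervals, res["tables"]["events"]
        )
        assert not (df.derepressed & ~df.increased_relative_expression).any()
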