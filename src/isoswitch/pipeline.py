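"""End-to-end orchestration of the analysis stages.

``run_cohort_analysis`` takes a dataset (simulated or loaded from files)
through: internal-priming filtering of 3'-end tracks -> TPM normalization
-> per-sample tag-cluster calling -> consensus aggregation -> spurious-TSS
filtering against the non-decapping control -> gene assignment ->
main/alternative classification and usage statistics -> per-cluster
differential expression -> switching / response calls -> internal-TSS and
truncated-ORF calls -> determinant table and regression.  Every stage
returns a plain DataFrame so intermediates are inspectable and diffable.

``run_derepression_analysis`` compares a mutant/control pair at one stage
with replicate-stratified CMH tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import assignment as asg
from . import clusters as cl
from . import derepression as der
from . import determinants as det
from . import diffexpr as de
from . import filters as flt
from . import internal_orfs as iorf
from . import switching as sw
from . import usage as usg
from .io import CoverageTrack, EndCountTrack, GeneModel, GenomeSequence
from .synthetic import SimulatedDataset

__all__ = [
    "PipelineConfig",
    "run_cohort_analysis",
    "run_derepression_analysis",
    "main_intervals_from_result",
]


def main_intervals_from_result(result: Dict) -> Dict[str, Tuple[int, int, str]]:
    """Per-gene main-TSS cluster intervals from a time-course run, in the
    form the mutant de-repression comparison consumes."""
    return {
        row.gene_id: (int(row.start), int(row.end), row.strand)
        for row in result["tables"]["main_clusters"].itertuples()
    }


@dataclass
class PipelineConfig:
    """All tunable thresholds, at their standard defaults."""

    tag_max_dist: int = 5
    singleton_floor_tpm: float = 3.0
    agg_tpm_threshold: float = 1.0
    q_low: float = 0.05
    q_up: float = 0.95
    agg_max_dist: int = 20
    assign_near: int = 100
    assign_far: int = 1000
    assign_window: int = 30
    tes_median_frac: float = 0.05
    tes_max_ratio: float = 5.0
    min_tpm: float = 1.0
    priming_motif_len: int = 20
    priming_max_mismatch: int = 8
    priming_max_dist: int = 5
    spurious_flank: int = 5
    spurious_r: float = 0.5
    spurious_p: float = 0.05
    min_orf_len: int = 300
    internal_fraction: float = 1.0 / 3.0
    distance_threshold: int = 80
    alt_percentile: float = 50.0
    main_percentile: float = 50.0
    seed: int = 0


def _call_consensus(
    tracks: Mapping[Tuple[str, str], EndCountTrack],
    kind: str,
    cfg: PipelineConfig,
    id_prefix: str,
) -> Tuple[List[cl.SiteCluster], Dict[str, cl.TpmTrack]]:
    """Per-strand tag clusters and consensus aggregation over all samples."""
    consensus: List[cl.SiteCluster] = []
    tpm_tracks: Dict[str, cl.TpmTrack] = {}
    for strand in "+-":
        strand_tracks = [
            t for (sid, s), t in sorted(tracks.items()) if s == strand
        ]
        tpms = [cl.normalize_tpm(t) for t in strand_tracks]
        for t in tpms:
            tpm_tracks[f"{t.sample_id}:{strand}"] = t
        per_sample = [
            cl.call_tag_clusters(
                t, cfg.tag_max_dist, cfg.singleton_floor_tpm, kind=kind
            )
            for t in tpms
        ]
        pooled = cl.pool_tracks(tpms)
        consensus.extend(
            cl.aggregate_clusters(
                per_sample,
                pooled,
                {t.sample_id: t for t in tpms},
                tpm_threshold=cfg.agg_tpm_threshold,
                q_low=cfg.q_low,
                q_up=cfg.q_up,
                max_dist=cfg.agg_max_dist,
                kind=kind,
                id_prefix=f"{id_prefix}{strand}",
            )
        )
    return consensus, tpm_tracks


def _raw_count_matrix(
    consensus: Sequence[cl.SiteCluster],
    tracks: Mapping[Tuple[str, str], EndCountTrack],
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    data = {}
    for sid in sample_ids:
        col = []
        for c in consensus:
            track = tracks[(sid, c.strand)]
            col.append(track.window_counts(c.contig, c.start, c.end).sum())
        data[sid] = col
    return pd.DataFrame(data, index=[c.cluster_id for c in consensus])


def _mean_tpm_by_timepoint(
    cluster: cl.SiteCluster, samples: Sequence[Tuple[str, str, int]]
) -> Dict[str, float]:
    by_tp: Dict[str, List[float]] = {}
    for sid, tp, _r in samples:
        by_tp.setdefault(tp, []).append(cluster.tpm_by_sample.get(sid, 0.0))
    return {tp: float(np.mean(v)) for tp, v in by_tp.items()}


def clusters_frame(consensus: Sequence[cl.SiteCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "contig": c.contig,
                "strand": c.strand,
                "start": c.start,
                "end": c.end,
                "apex": c.apex,
                "kind": c.kind,
            }
            for c in consensus
        ]
    )


def run_cohort_analysis(
    dataset: SimulatedDataset,
    cfg: Optional[PipelineConfig] = None,
) -> Dict[str, object]:
    """Run every time-course stage; returns tables plus live objects.

    The returned dict contains DataFrames under ``tables`` (stable,
    serializable outputs) and intermediate objects (consensus clusters,
    usage roles, DE lookups) under their own keys for downstream reuse.
    """
    cfg = cfg or PipelineConfig()
    spec = dataset.spec
    params = spec.params
    reference = params.reference
    transition_tps = list(params.timepoints[1:])
    sample_ids = [sid for sid, _tp, _r in dataset.samples]

    # --- 3'-end artifact filtering happens before TES cluster calling
    tracts = flt.find_polya_tracts(
        spec.genome, cfg.priming_motif_len, cfg.priming_max_mismatch
    )
    tes_filtered: Dict[Tuple[str, str], EndCountTrack] = {
        key: flt.filter_internal_priming(track, tracts, cfg.priming_max_dist)
        for key, track in dataset.tes.items()
    }
    for sid in sample_ids:  # library = strand-pair total after filtering
        total = tes_filtered[(sid, "+")].total() + tes_filtered[(sid, "-")].total()
        for strand in "+-":
            tes_filtered[(sid, strand)].library_size = max(total, 1)

    # --- cluster calling
    tss_clusters, _ = _call_consensus(dataset.tss, "TSS", cfg, "tss")
    tes_clusters, _ = _call_consensus(tes_filtered, "TES", cfg, "tes")

    # --- spurious-TSS filter against the non-decapping control
    ref_sample = f"{reference}_rep1"
    spurious_rows = []
    kept_tss: List[cl.SiteCluster] = []
    for c in tss_clusters:
        call = flt.flag_spurious_tss(
            c,
            dataset.tss[(ref_sample, c.strand)],
            dataset.nondecapped[c.strand],
            flank=cfg.spurious_flank,
            r_threshold=cfg.spurious_r,
            p_threshold=cfg.spurious_p,
            contig_length=spec.genome.length(c.contig),
        )
        spurious_rows.append(
            {
                "cluster_id": c.cluster_id,
                "spearman_r": call.spearman_r,
                "p_value": call.p_value,
                "spurious": call.spurious,
            }
        )
        if not call.spurious:
            kept_tss.append(c)

    all_clusters = kept_tss + tes_clusters
    by_id = {c.cluster_id: c for c in all_clusters}

    # --- gene assignment, mRNA coverage at the cluster's peak timepoint
    assignments: List[asg.GeneAssignment] = []
    for c in all_clusters:
        tpm_by_tp = _mean_tpm_by_timepoint(c, dataset.samples)
        peak_tp = max(tpm_by_tp, key=lambda tp: (tpm_by_tp[tp], tp))
        coverage = dataset.coverage[peak_tp]
        fn = asg.assign_tss if c.kind == "TSS" else asg.assign_tes
        kwargs = dict(
            near_dist=cfg.assign_near,
            far_dist=cfg.assign_far,
            window=cfg.assign_window,
        )
        if c.kind == "TES":
            kwargs.update(
                median_frac=cfg.tes_median_frac, max_ratio=cfg.tes_max_ratio
            )
        a = fn(c, spec.genes, coverage, **kwargs)
        if a is not None:
            assignments.append(a)
    assign_df = pd.DataFrame(
        [
            {
                "cluster_id": a.cluster_id,
                "gene_id": a.gene_id,
                "category": a.category,
                "distance": a.distance_to_feature,
                "utr_length": a.utr_length,
                "kind": by_id[a.cluster_id].kind,
            }
            for a in assignments
        ]
    )

    # --- cluster expression per gene (replicate-averaged TPM)
    clusters_by_gene: Dict[str, List[usg.ClusterExpression]] = {}
    for a in assignments:
        c = by_id[a.cluster_id]
        if c.kind != "TSS":
            continue
        clusters_by_gene.setdefault(a.gene_id, []).append(
            usg.ClusterExpression(
                cluster_id=c.cluster_id,
                gene_id=a.gene_id,
                apex=c.apex,
                strand=c.strand,
                category=a.category,
                tpm=_mean_tpm_by_timepoint(c, dataset.samples),
            )
        )

    # --- differential expression, each transition timepoint vs reference
    counts_tss = _raw_count_matrix(tss_clusters, dataset.tss, sample_ids)
    diff_tables: Dict[str, pd.DataFrame] = {}
    for tp in transition_tps:
        t_cols = [sid for sid, tpt, _ in dataset.samples if tpt == tp]
        r_cols = [sid for sid, tpt, _ in dataset.samples if tpt == reference]
        diff_tables[tp] = de.run_differential_expression(
            counts_tss, t_cols, r_cols, comparison=f"{tp}_vs_{reference}"
        )
    diff = sw.DiffLookup(diff_tables)

    # --- usage, switching
    config = usg.TransitionConfig("T", reference, tuple(transition_tps))
    usage_df = usg.build_usage_table(clusters_by_gene, config, cfg.min_tpm)
    events_df = sw.run_switching_analysis(clusters_by_gene, config, diff, cfg.min_tpm)
    internal_events = []
    for gene_id, gcs in sorted(clusters_by_gene.items()):
        internal_events.extend(
            sw.internal_to_promoter_switch(gcs, config, diff, cfg.min_tpm)
        )
    internal_events_df = pd.DataFrame([e.__dict__ for e in internal_events])

    # --- internal TSSs and truncated ORFs
    gene_by_id = {g.gene_id: g for g in spec.genes}
    internal_rows = []
    for gene_id, gcs in sorted(clusters_by_gene.items()):
        gene = gene_by_id[gene_id]
        main_id = usg.define_main(gcs, config, cfg.min_tpm)
        for ce in gcs:
            if ce.category != "internal":
                continue
            c = by_id[ce.cluster_id]
            rows = [diff.get(tp, ce.cluster_id) for tp in transition_tps]
            relaxed = iorf.relaxed_filter(rows)
            orf = iorf.predict_orf(spec.genome, c.apex, gene, cfg.min_orf_len)
            leader = iorf.leader_length(spec.genome, c.apex, gene)
            stringent = False
            fraction = None
            if relaxed and main_id is not None and main_id != ce.cluster_id:
                main_tpm_by_tp = next(
                    g.tpm for g in gcs if g.cluster_id == main_id
                )
                fired = [
                    tp
                    for tp, row in zip(transition_tps, rows)
                    if row is not None and sw._sig_up(row)
                ]
                best_tp = max(fired, key=lambda tp: ce.tpm.get(tp, 0.0))
                mt = main_tpm_by_tp.get(best_tp, 0.0)
                fraction = ce.tpm.get(best_tp, 0.0) / mt if mt > 0 else None
                stringent = iorf.stringent_filter(
                    relaxed,
                    ce.tpm.get(best_tp, 0.0),
                    mt if mt > 0 else None,
                    orf,
                    cfg.internal_fraction,
                    cfg.min_orf_len,
                )
            internal_rows.append(
                {
                    "cluster_id": ce.cluster_id,
                    "gene_id": gene_id,
                    "relaxed": relaxed,
                    "stringent": stringent,
                    "fraction_of_full_length": fraction,
                    "orf_length": orf.length if orf else None,
                    "orf_start": orf.start if orf else None,
                    "orf_end": orf.end if orf else None,
                    "leader_length": leader,
                }
            )
    internal_df = pd.DataFrame(internal_rows)

    # --- determinants of main-TSS response
    pairs = sw.build_pairs(clusters_by_gene, config, cfg.min_tpm)
    agg_tp = transition_tps[-1]
    records = det.build_determinant_table(
        pairs, diff, agg_tp, reference, dataset.occupancy, seed=cfg.seed
    )
    regression = None
    if len(records) > 6:
        regression = det.fit_multiple_regression(records)
    proximal, distal = det.split_by_distance(records, cfg.distance_threshold)
    distance_stats = det.correlate_and_test(records, other=None)
    if len(proximal) >= 3 and len(distal) >= 3:
        distance_stats.update(
            {
                f"split_{k}": v
                for k, v in det.correlate_and_test(
                    proximal, other=distal
                ).items()
            }
        )

    main_rows = []
    for gene_id, gcs in sorted(clusters_by_gene.items()):
        mid = usg.define_main(gcs, config, cfg.min_tpm)
        if mid is not None:
            c = by_id[mid]
            main_rows.append(
                {
                    "gene_id": gene_id,
                    "cluster_id": mid,
                    "start": c.start,
                    "end": c.end,
                    "strand": c.strand,
                }
            )

    tables: Dict[str, pd.DataFrame] = {
        "main_clusters": pd.DataFrame(main_rows),
        "tss_clusters": clusters_frame(tss_clusters),
        "tes_clusters": clusters_frame(tes_clusters),
        "spurious_calls": pd.DataFrame(spurious_rows),
        "assignments": assign_df,
        "usage": usage_df,
        "events": events_df,
        "internal_events": internal_events_df,
        "internal_calls": internal_df,
        "determinants": det.records_to_frame(records),
    }
    for tp, df in diff_tables.items():
        tables[f"diff_{tp}"] = df
    return {
        "tables": tables,
        "tss_clusters": tss_clusters,
        "kept_tss": kept_tss,
        "tes_clusters": tes_clusters,
        "assignments": assignments,
        "clusters_by_gene": clusters_by_gene,
        "diff": diff,
        "config": config,
        "pairs": pairs,
        "records": records,
        "regression": regression,
        "distance_stats": distance_stats,
        "counts_tss": counts_tss,
    }


# ---------------------------------------------------------------------------
# mutant vs control


def run_derepression_analysis(
    control: SimulatedDataset,
    mutant: SimulatedDataset,
    main_intervals: Mapping[str, Tuple[int, int, str]],
    control_events: pd.DataFrame,
    cfg: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """CMH-based differential TSS usage between genotypes at one stage.

    ``main_intervals`` gives, per gene, the time-course main TSS cluster
    interval (start, end, strand) from the control analysis;
    ``control_events`` is the control time-course pair-level event table.
    Replicates pair across genotypes by index.
    """
    cfg = cfg or PipelineConfig()
    spec = control.spec
    stage = spec.params.timepoints[0]

    control_clusters, _ = _call_consensus(control.tss, "TSS", cfg, "ctl")
    mutant_clusters, _ = _call_consensus(mutant.tss, "TSS", cfg, "mut")
    mapping = der.map_clusters(mutant_clusters, control_clusters)

    coverage = control.coverage[stage]
    control_assign = {
        a.cluster_id: a
        for a in asg.assign_all(control_clusters, spec.genes, coverage)
    }
    # mutant-only clusters are assigned to genes de novo
    mutant_only = [
        c for c in mutant_clusters if mapping.get(c.cluster_id) is None
    ]
    mutant_only_assign = {
        a.cluster_id: a for a in asg.assign_all(mutant_only, spec.genes, coverage)
    }

    by_gene: Dict[str, List[cl.SiteCluster]] = {}
    cluster_index = {c.cluster_id: c for c in control_clusters + mutant_clusters}
    for cid, a in list(control_assign.items()) + list(mutant_only_assign.items()):
        by_gene.setdefault(a.gene_id, []).append(cluster_index[cid])

    n_rep = spec.params.n_replicates
    stacks: Dict[str, der.ContingencyStack] = {}
    usage_rows = []
    for gene_id, gene_clusters in sorted(by_gene.items()):
        mi = main_intervals.get(gene_id)
        if mi is None:
            continue
        m_start, m_end, m_strand = mi
        main = None
        for c in gene_clusters:
            if c.strand == m_strand and min(c.end, m_end) - max(c.start, m_start) > 0:
                main = c
                break
        if main is None or len(gene_clusters) < 2:
            continue
        alts = [c for c in gene_clusters if c.cluster_id != main.cluster_id]
        stack = der.ContingencyStack(gene_id)
        for r in range(1, n_rep + 1):
            sid = f"{stage}_rep{r}"

            def counts_in(ds: SimulatedDataset, c: cl.SiteCluster) -> int:
                tr = ds.tss[(sid, c.strand)]
                return int(tr.window_counts(c.contig, c.start, c.end).sum())

            stack.add_stratum(
                counts_in(control, main),
                counts_in(mutant, main),
                sum(counts_in(control, c) for c in alts),
                sum(counts_in(mutant, c) for c in alts),
            )
        stacks[gene_id] = stack
        # TPM-scale relative main usage for reporting
        for label, ds in (("control", control), ("mutant", mutant)):
            tpms = []
            main_tpm = 0.0
            for c in [main] + alts:
                tot = 0.0
                for r in range(1, n_rep + 1):
                    tr = ds.tss[(f"{stage}_rep{r}", c.strand)]
                    tot += (
                        tr.window_counts(c.contig, c.start, c.end).sum()
                        / tr.library_size
                        * 1e6
                    )
                tpms.append(tot / n_rep)
            main_tpm = tpms[0]
            usage_rows.append(
                {
                    "gene_id": gene_id,
                    "genotype": label,
                    "relative_main_usage": der.relative_main_usage(main_tpm, tpms),
                }
            )

    results = der.call_derepression(stacks, control_events)
    df = pd.DataFrame([r.__dict__ for r in results])
    usage_df = pd.DataFrame(usage_rows)
    if not df.empty and not usage_df.empty:
        wide = usage_df.pivot(
            index="gene_id", columns="genotype", values="relative_main_usage"
        )
        df = df.merge(
            wide.rename(
                columns={
                    "control": "tpm_main_usage_control",
                    "mutant": "tpm_main_usage_mutant",
                }
            ),
            on="gene_id",
            how="left",
        )
    return df
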