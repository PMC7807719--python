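"""Distance-based clustering of single-nucleotide end positions.

Per-sample positions with nonzero signal are grouped whenever consecutive
nonzero positions lie within ``max_dist`` of each other (the CAGE-style
"distclu" rule); singleton groups survive only above a TPM floor.  Retained
per-sample clusters are then merged across samples into consensus clusters
whose boundaries are trimmed to the central mass of the pooled signal
between two cumulative quantiles.

Default parameters (``max_dist=5``, ``singleton_floor_tpm=3`` for tag
clusters; ``tpm_threshold=1``, ``q_low=0.05``, ``q_up=0.95``, ``max_dist=20``
for aggregation) are the values used for yeast 5'/3'-end data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .io import EndCountTrack

__all__ = [
    "TpmTrack",
    "SiteCluster",
    "normalize_tpm",
    "pool_tracks",
    "call_tag_clusters",
    "aggregate_clusters",
    "cluster_apex",
]


@dataclass
class TpmTrack:
    """A per-base track on the tags-per-million scale (floats >= 0)."""

    sample_id: str
    timepoint: str
    replicate: int
    strand: str
    values: Dict[str, Dict[int, float]] = field(default_factory=dict)

    def window_sum(self, contig: str, start: int, end: int) -> float:
        # accumulate in position order so the float sum is independent of
        # dict insertion order (simulated vs file-loaded tracks)
        vals = self.values.get(contig, {})
        return float(
            sum(v for _p, v in sorted((p, v) for p, v in vals.items() if start <= p < end))
        )


@dataclass
class SiteCluster:
    """A contiguous clustered TSS or TES region.

    ``start``/``end`` are 0-based half-open (quantile-trimmed for consensus
    clusters); ``apex`` is the position of maximal pooled signal inside the
    cluster; ``tpm_by_sample`` quantifies the cluster per sample over
    ``[start, end)``.
    """

    cluster_id: str
    contig: str
    strand: str
    start: int
    end: int
    apex: int
    tpm_by_sample: Dict[str, float] = field(default_factory=dict)
    kind: str = "TSS"

    def __post_init__(self) -> None:
        if not (self.start <= self.apex < self.end):
            raise ValueError(
                f"cluster {self.cluster_id}: apex {self.apex} outside "
                f"[{self.start}, {self.end})"
            )

    @property
    def total_tpm(self) -> float:
        return float(sum(self.tpm_by_sample.values()))

    def max_sample_tpm(self) -> float:
        return max(self.tpm_by_sample.values()) if self.tpm_by_sample else 0.0


def normalize_tpm(track: EndCountTrack) -> TpmTrack:
    """Scale raw end counts to tags per million of the sample library."""
    if track.library_size <= 0:
        raise ValueError("empty library: library_size must be > 0")
    scale = 1e6 / track.library_size
    values = {
        contig: {pos: c * scale for pos, c in positions.items() if c > 0}
        for contig, positions in track.counts.items()
    }
    return TpmTrack(
        sample_id=track.sample_id,
        timepoint=track.timepoint,
        replicate=track.replicate,
        strand=track.strand,
        values=values,
    )


def pool_tracks(tracks: Sequence[TpmTrack]) -> TpmTrack:
    """Position-wise sum of several TPM tracks of the same strand."""
    if not tracks:
        raise ValueError("no tracks to pool")
    strand = tracks[0].strand
    pooled: Dict[str, Dict[int, float]] = {}
    for tr in tracks:
        if tr.strand != strand:
            raise ValueError("cannot pool tracks of mixed strand")
        for contig, vals in tr.values.items():
            dest = pooled.setdefault(contig, {})
            for pos, v in vals.items():
                dest[pos] = dest.get(pos, 0.0) + v
    return TpmTrack(
        sample_id="pooled", timepoint="", replicate=0, strand=strand, values=pooled
    )


def _group_positions(positions: np.ndarray, max_dist: int) -> List[np.ndarray]:
    """Split sorted positions into runs with inter-neighbor gaps <= max_dist."""
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > max_dist) + 1
    return np.split(positions, breaks)


def call_tag_clusters(
    track: TpmTrack,
    max_dist: int = 5,
    singleton_floor_tpm: float = 3.0,
    kind: str = "TSS",
) -> List[SiteCluster]:
    """Group nonzero positions of one sample into tag clusters.

    Two nonzero positions p < q belong to the same cluster when every gap
    between consecutive nonzero positions on the path from p to q is
    <= ``max_dist``.  A cluster containing a single position is kept only if
    its TPM >= ``singleton_floor_tpm`` (inclusive).
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    clusters: List[SiteCluster] = []
    for contig in sorted(track.values):
        vals = track.values[contig]
        positions = np.array(sorted(p for p, v in vals.items() if v > 0))
        for group in _group_positions(positions, max_dist):
            tpm = float(sum(vals[p] for p in group))
            if len(group) == 1 and tpm < singleton_floor_tpm:
                continue
            start, end = int(group[0]), int(group[-1]) + 1
            apex = _argmax_position(
                {int(p): vals[int(p)] for p in group}, track.strand
            )
            clusters.append(
                SiteCluster(
                    cluster_id=f"{track.sample_id}:{contig}:{track.strand}:{start}",
                    contig=contig,
                    strand=track.strand,
                    start=start,
                    end=end,
                    apex=apex,
                    tpm_by_sample={track.sample_id: tpm},
                    kind=kind,
                )
            )
    return clusters


def _argmax_position(values: Dict[int, float], strand: str) -> int:
    """Position of maximal signal; ties break to the 5'-most base."""
    best = None
    best_val = -np.inf
    items = sorted(values.items())
    if strand == "-":
        items = items[::-1]
    for pos, v in items:
        if v > best_val:
            best, best_val = pos, v
    return int(best)


def cluster_apex(cluster: SiteCluster, pooled: TpmTrack) -> int:
    """Apex of a cluster from the pooled track: argmax, 5'-most on ties."""
    vals = pooled.values.get(cluster.contig, {})
    window = {
        p: v for p, v in vals.items() if cluster.start <= p < cluster.end and v > 0
    }
    if not window:
        raise ValueError(f"cluster {cluster.cluster_id} has zero pooled signal")
    return _argmax_position(window, cluster.strand)


def _quantile_trim(
    positions: np.ndarray, weights: np.ndarray, q_low: float, q_up: float
) -> Tuple[int, int]:
    """Smallest subinterval holding the pooled mass between two quantiles.

    Positions are walked 5'->3' in genomic coordinates; the kept interval is
    [first position with cumulative fraction strictly above q_low, last
    position with cumulative fraction <= q_up], extended outward if needed
    so that it never holds less than (q_up - q_low) of the total mass.
    """
    total = weights.sum()
    cum = np.cumsum(weights) / total
    eps = 1e-12
    low_candidates = np.flatnonzero(cum > q_low + eps)
    low_idx = int(low_candidates[0]) if len(low_candidates) else 0
    high_candidates = np.flatnonzero(cum <= q_up + eps)
    high_idx = int(high_candidates[-1]) if len(high_candidates) else -1
    if high_idx < low_idx:
        high_idx = low_idx
    target = (q_up - q_low) - eps
    while (
        cum[high_idx] - (cum[low_idx - 1] if low_idx > 0 else 0.0) < target
        and high_idx < len(positions) - 1
    ):
        high_idx += 1
    return int(positions[low_idx]), int(positions[high_idx]) + 1


def aggregate_clusters(
    per_sample: Sequence[Sequence[SiteCluster]],
    pooled: TpmTrack,
    tracks_by_sample: Dict[str, TpmTrack],
    tpm_threshold: float = 1.0,
    q_low: float = 0.05,
    q_up: float = 0.95,
    max_dist: int = 20,
    kind: str = "TSS",
    id_prefix: str = "c",
) -> List[SiteCluster]:
    """Merge per-sample tag clusters into quantile-trimmed consensus clusters.

    Per-sample clusters below ``tpm_threshold`` in their own sample are
    discarded; survivors whose untrimmed spans are within ``max_dist`` of
    each other (transitively, same contig/strand) merge into one consensus
    cluster.  Boundaries are then trimmed to the smallest interval holding
    the pooled cumulative mass between ``q_low`` and ``q_up``; the apex is
    the position of maximal pooled signal inside the trimmed interval, and
    per-sample TPMs are re-summed over the trimmed interval.
    """
    if q_low >= q_up:
        raise ValueError("q_low must be < q_up")
    retained = [
        c
        for sample in per_sample
        for c in sample
        if c.max_sample_tpm() >= tpm_threshold
    ]
    by_contig: Dict[str, List[SiteCluster]] = {}
    for c in retained:
        by_contig.setdefault(c.contig, []).append(c)

    consensus: List[SiteCluster] = []
    counter = 0
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig], key=lambda c: (c.start, c.end))
        # transitive span merge: gap between consecutive spans <= max_dist
        groups: List[List[SiteCluster]] = []
        cur: List[SiteCluster] = []
        cur_end = None
        for c in members:
            if cur and c.start - cur_end > max_dist:
                groups.append(cur)
                cur = []
                cur_end = None
            cur.append(c)
            cur_end = c.end if cur_end is None else max(cur_end, c.end)
        if cur:
            groups.append(cur)

        pooled_vals = pooled.values.get(contig, {})
        for group in groups:
            span_start = min(c.start for c in group)
            span_end = max(c.end for c in group)
            positions = np.array(
                sorted(
                    p
                    for p, v in pooled_vals.items()
                    if span_start <= p < span_end and v > 0
                )
            )
            if len(positions) == 0:
                continue
            weights = np.array([pooled_vals[int(p)] for p in positions])
            start, end = _quantile_trim(positions, weights, q_low, q_up)
            window = {
                int(p): pooled_vals[int(p)]
                for p in positions
                if start <= p < end
            }
            apex = _argmax_position(window, pooled.strand)
            tpm_by_sample = {
                sid: tr.window_sum(contig, start, end)
                for sid, tr in tracks_by_sample.items()
            }
            counter += 1
            consensus.append(
                SiteCluster(
                    cluster_id=f"{id_prefix}{counter:05d}",
                    contig=contig,
                    strand=pooled.strand,
                    start=start,
                    end=end,
                    apex=apex,
                    tpm_by_sample=tpm_by_sample,
                    kind=kind,
                )
            )
    return consensus
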