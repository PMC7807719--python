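"""Shared fixtures: tiny genomes, tracks, and a small simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest

from isoswitch.io import CoverageTrack, EndCountTrack, GeneModel, GenomeSequence
from isoswitch.synthetic import CohortParams, build_cohort_spec, simulate_tracks


@pytest.fixture
def plus_gene() -> GeneModel:
    return GeneModel("geneA", "chr1", "+", 1000, 1900)


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel("geneB", "chr1", "-", 3000, 3900)


@pytest.fixture
def flat_coverage() -> CoverageTrack:
    """Uniform coverage 5.0 everywhere on a 10 kb contig, both strands."""
    arr = np.full(10_000, 5.0, dtype=np.float32)
    return CoverageTrack(
        plus={"chr1": arr.copy()}, minus={"chr1": arr.copy()}
    )


def make_track(counts, strand="+", contig="chr1", sample_id="s1", **kw):
    track = EndCountTrack(
        sample_id=sample_id,
        timepoint=kw.get("timepoint", "t0"),
        replicate=kw.get("replicate", 1),
        strand=strand,
    )
    for pos, c in counts.items():
        track.add(contig, pos, c)
    track.library_size = kw.get("library_size", track.total())
    return track


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort exercising every planted class (session cached)."""
    params = CohortParams(
        n_repressed=15,
        n_coactivated=15,
        n_neutral=15,
        n_stable=40,
        n_internal_switch=6,
        n_internal_induced=6,
        n_spurious=6,
        n_priming=8,
        n_filler=40,
    )
    spec = build_cohort_spec(params, seed=11)
    dataset = simulate_tracks(spec, seed=12)
    return spec, dataset


@pytest.fixture(scope="session")
def small_cohort_result(small_cohort):
    from isoswitch.pipeline import run_cohort_analysis

    _spec, dataset = small_cohort
    return run_cohort_analysis(dataset)
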