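"""Shared fixtures: synthetic pangenomes at two scales and one finished run.

The expensive pieces (the standard 20-genome fixture and its pipeline run)
are session-scoped so the recovery, nesting, conservation and determinism
checks all share one computation.
"""

from __future__ import annotations

import pytest

from pangraphe.annotation_io import Locus
from pangraphe.config import PipelineConfig
from pangraphe.pipeline import run_pipeline
from pangraphe.simulate import (DuplicationEvent, FissionEvent,
                                SimulationSpec, default_fixture_spec,
                                simulate)


def make_locus(locus_id: str, aa_seq: str = "", nt_seq: str = "",
               genome_id: str = "G01", contig_id: str = "c1",
               start: int = 1, strand: str = "+",
               feature_type: str = "CDS", product: str = "") -> Locus:
    """Construct a consistent Locus from either an aa or nt sequence."""
    if not nt_seq:
        nt_seq = "A" * (3 * len(aa_seq))  # placeholder; aa_seq drives tests
    return Locus(
        locus_id=locus_id, genome_id=genome_id, contig_id=contig_id,
        start=start, end=start + len(nt_seq) - 1, strand=strand,
        feature_type=feature_type, product=product,
        nt_seq=nt_seq, aa_seq=aa_seq)


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    return SimulationSpec(
        n_genomes=4, n_families=8, target_identities=(60.0, 95.0),
        duplications=(DuplicationEvent(family=1, genome=0),),
        fissions=(FissionEvent(family=2, genome=1),), seed=5)


@pytest.fixture(scope="session")
def small_sim(small_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim_small")
    paths, truth = simulate(small_spec, out)
    return out, paths, truth


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    sim_dir, _, truth = small_sim
    out = tmp_path_factory.mktemp("run_small")
    result = run_pipeline(sim_dir, out, config=PipelineConfig())
    return result, truth, out


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim_default")
    paths, truth = simulate(default_fixture_spec(seed=20), out)
    return out, paths, truth


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    sim_dir, _, truth = default_sim
    out = tmp_path_factory.mktemp("run_default")
    result = run_pipeline(sim_dir, out, config=PipelineConfig())
    return result, truth, out
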