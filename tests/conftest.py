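"""Shared fixtures: a small synthetic lymph node and helpers."""

import pytest

from gcrepertoire.clones import group_clones
from gcrepertoire.io import RearrangementRecord
from gcrepertoire.simulate import LymphNodeConfig, generate_lymph_node


@pytest.fixture(scope="session")
def small_ln():
    """A small but complete lymph node: 10 GCs x 2 replicates, ~8,000 cells."""
    cfg = LymphNodeConfig(seqs_per_sample=400, n_clones_per_gc=100, seed=11)
    records, truth = generate_lymph_node(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_clones(small_ln):
    _, records, _ = small_ln
    return group_clones(records)


@pytest.fixture(scope="session")
def rec_map(small_ln):
    _, records, _ = small_ln
    return {r.sequence_id: r for r in records}


def make_record(
    sequence_id: str,
    junction: str,
    *,
    sequence: str | None = None,
    v_call: str = "IGHV1-2*01",
    j_call: str = "IGHJ4*01",
    gc_id: str = "GC1",
    replicate_id: str = "R1",
    duplicate_count: int = 1,
    in_frame: bool = True,
    region_bounds: dict | None = None,
    n_region_bounds: list | None = None,
) -> RearrangementRecord:
    """A minimal hand-built record for unit tests."""
    return RearrangementRecord(
        sequence_id=sequence_id,
        gc_id=gc_id,
        replicate_id=replicate_id,
        sequence=sequence if sequence is not None else junction,
        v_call=v_call,
        j_call=j_call,
        junction=junction,
        junction_length=len(junction),
        region_bounds=region_bounds or {},
        n_region_bounds=n_region_bounds or [],
        in_frame_junction=in_frame,
        duplicate_count=duplicate_count,
    )
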