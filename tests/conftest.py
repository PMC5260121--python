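"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import pytest

from ervpipe.synthetic_data import ConsensusSet, SimConfig, make_consensus_set, simulate_genome


@pytest.fixture(scope="session")
def consensus_set() -> ConsensusSet:
    return make_consensus_set(seed=0)


TINY_CONFIG = SimConfig(
    n_chroms=2,
    chrom_len=400_000,
    counts={"full_length": 6, "solo_ltr": 10, "truncated": 4, "chimeric": 1},
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_sim():
    """A small planted genome shared across read-only tests."""
    return simulate_genome(TINY_CONFIG)


@pytest.fixture(scope="session")
def tiny_sim_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("tiny_sim")
    from ervpipe.synthetic_data import write_sim_outputs

    result = simulate_genome(TINY_CONFIG)
    write_sim_outputs(result, outdir)
    return outdir, result
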