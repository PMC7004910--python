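"""Shared fixtures: one small simulated arm reused across test modules."""

import numpy as np
import pytest

from armcompare.synthetic_data import (SimulationConfig, evolve_derived,
                                       fragment_assembly, simulate_ancestor,
                                       simulate_markers)

TINY = SimulationConfig(
    seed=11, arm_length=300_000, n_genes=30, n_gaps=10, n_markers=8,
    n_qtls=4, te_fraction=0.5,
)


@pytest.fixture(scope="session")
def tiny_ancestor():
    return simulate_ancestor(TINY)


@pytest.fixture(scope="session")
def tiny_derived(tiny_ancestor):
    return evolve_derived(tiny_ancestor, TINY)


@pytest.fixture(scope="session")
def tiny_fragmented(tiny_ancestor):
    return fragment_assembly(tiny_ancestor.record, TINY,
                             tiny_ancestor.genes, tiny_ancestor.truth)


@pytest.fixture(scope="session")
def tiny_markers(tiny_ancestor, tiny_fragmented):
    marker_df, qtl_df, truth = simulate_markers(
        tiny_ancestor.record, TINY, list(tiny_fragmented.assembly.gaps),
        tiny_ancestor.truth)
    return marker_df, qtl_df, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
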