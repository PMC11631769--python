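"""Shared fixtures: one small genome and a few simulated datasets reused
across test modules (session-scoped; all generation is seeded)."""

from __future__ import annotations

import numpy as np
import pytest

import karyoclone as kc
from karyoclone.scenarios import ck_branched_tree


@pytest.fixture(scope="session")
def genome():
    return kc.toy_genome(seed=0)


@pytest.fixture(scope="session")
def linear_tree(genome):
    return kc.build_clone_tree("linear", 3, 2, genome, seed=1)


@pytest.fixture(scope="session")
def branched_tree(genome):
    return kc.build_clone_tree("branched", 5, 2, genome, seed=3)


@pytest.fixture(scope="session")
def linear_strand(genome, linear_tree):
    cfg = kc.SimConfig(seed=5, n_strand_cells=120)
    return kc.simulate_strand_cells(linear_tree, genome, cfg)


@pytest.fixture(scope="session")
def linear_called(linear_strand):
    states, segments, genotypes, calls = kc.call_svs(linear_strand)
    return {
        "states": states,
        "segments": segments,
        "genotypes": genotypes,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def ck_scenario():
    genome, tree = ck_branched_tree()
    cfg = kc.SimConfig(seed=11, n_strand_cells=150, n_expr_cells=1200)
    strand = kc.simulate_strand_cells(tree, genome, cfg)
    expr = kc.simulate_expression_cells(tree, genome, cfg)
    return genome, tree, strand, expr


@pytest.fixture()
def rng():
    # fresh deterministic stream per test: results do not depend on test order
    return np.random.default_rng(1234)
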