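"""Shared fixtures: tiny hand-built DAGs and a reusable synthetic world."""

import numpy as np
import pytest

from goaqc.ontology import OntologyDag, OntologyTerm
from goaqc.synthesis import (
    FixtureWorldConfig,
    generate_fixture_world,
    split_by_pmid,
    synthesize_balanced_corpus,
)


def make_dag(edges, extra_terms=()):
    """Build a DAG from (child, parent, relation) triples, declaring terms."""
    ids = {e[0] for e in edges} | {e[1] for e in edges} | set(extra_terms)
    terms = [OntologyTerm(id=i, name=f"name {i}") for i in sorted(ids)]
    return OntologyDag(terms, edges)


@pytest.fixture
def chain_dag():
    # C -> B -> A
    return make_dag([("T:3", "T:2", "is_a"), ("T:2", "T:1", "is_a")])


@pytest.fixture
def diamond_dag():
    # D -> {B, C}, B -> A, C -> A
    return make_dag(
        [
            ("T:4", "T:2", "is_a"),
            ("T:4", "T:3", "part_of"),
            ("T:2", "T:1", "is_a"),
            ("T:3", "T:1", "is_a"),
        ]
    )


SMALL_WORLD_CFG = FixtureWorldConfig(
    n_terms=120,
    depth=5,
    n_genes=30,
    n_gene_families=5,
    n_instances=150,
    distractor_go_rate=1.0,
    distractor_gene_rate=1.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_world():
    return generate_fixture_world(SMALL_WORLD_CFG)


@pytest.fixture(scope="session")
def small_corpus(small_world):
    return synthesize_balanced_corpus(
        small_world.instances,
        20,
        small_world.dag,
        seed=7,
        gene_background=small_world.gene_background,
    )


@pytest.fixture(scope="session")
def small_splits(small_corpus):
    return split_by_pmid(small_corpus, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
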