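"""Shared fixtures: a scaled-down synthetic plasmid dataset.

The small configuration keeps the structure of the standard study
conditions (backbone cliques, two related-backbone chains, a shared
mobile-element pool, singletons, a chimera) at kilobase scale so the whole
matrix is computed in seconds. The shared-k-mer cutoff is scaled with the
backbone length, as the generator manifest records.
"""

from __future__ import annotations

import pytest

import plasmidnet as pn

SMALL_CONFIG = pn.SimulationConfig(
    n_cliques=6,
    clique_size_range=(4, 7),
    backbone_length_range=(3_000, 5_000),
    n_elements=4,
    element_length_range=(200, 400),
    element_insertion_prob=0.15,
    accessory_length_range=(150, 300),
    n_chains=2,
    chain_length=3,
    n_singletons=4,
    singleton_length_range=(1_000, 2_000),
    n_chimeras=1,
    seed=11,
)


@pytest.fixture(scope="session")
def small_dataset() -> pn.SyntheticDataset:
    return pn.simulate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_matrix(small_dataset) -> pn.SimilarityMatrix:
    kmersets = [pn.extract_kmers(r) for r in small_dataset.records]
    return pn.pairwise_jaccard(
        kmersets, min_shared=small_dataset.manifest["min_shared"]
    )


@pytest.fixture(scope="session")
def small_original(small_matrix):
    return pn.build_network(small_matrix, 0.0)


@pytest.fixture(scope="session")
def small_cliques(small_matrix, small_original) -> pn.CliqueSet:
    """Detected + validated cliques on the small dataset at JI 0.05."""
    network = pn.build_network(small_matrix, 0.05)
    communities = pn.detect_communities(
        network, pn.DetectionConfig(n_runs=10, seed=42)
    )
    return pn.validate_cliques(communities, small_original)
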