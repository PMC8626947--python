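"""Shared fixtures: synthetic communities generated once per session."""

from __future__ import annotations

import pytest

from peatvirome import votu
from peatvirome.simulate import TruthConfig, generate_community


@pytest.fixture(scope="session")
def toy_config() -> TruthConfig:
    """Small community with oracle-friendly (~2 kb) genomes."""
    return TruthConfig(
        seed=7,
        n_genera=3,
        species_per_genus=4,
        variants_per_species=3,
        genome_len_range=(1500, 2000),
        n_hosts=6,
        n_samples=12,
        da_group_sizes=(4, 3, 3),
        library_size_range=(2000, 3000),
    )


@pytest.fixture(scope="session")
def toy_community(toy_config):
    contigs, proteins, gmap, habitat, truth = generate_community(toy_config)
    return {
        "config": toy_config,
        "contigs": contigs,
        "proteins": proteins,
        "genome_map": gmap,
        "habitat": habitat,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_config() -> TruthConfig:
    """The study-scale default design."""
    return TruthConfig(seed=0)


@pytest.fixture(scope="session")
def default_community(default_config):
    contigs, proteins, gmap, habitat, truth = generate_community(default_config)
    return {
        "config": default_config,
        "contigs": contigs,
        "proteins": proteins,
        "genome_map": gmap,
        "habitat": habitat,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_votu_clusters(default_community):
    return votu.greedy_cluster(default_community["contigs"])
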