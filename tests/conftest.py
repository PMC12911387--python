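import numpy as np
import pytest

from defcom.community import (
    AbundanceModel,
    CommunityConfig,
    LineageSpec,
    PlantedFeature,
    build_community,
    generate_host_decoy,
    make_design,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_community():
    """6 strains in 3 lineages (3+2+1), 60 kb genomes, with planted
    endosphere markers in the first two lineages."""
    cfg = CommunityConfig(
        lineages=[LineageSpec(3, 0.004), LineageSpec(2, 0.004), LineageSpec(1, 0.004)],
        genome_length=60_000,
        n_genes=50,
        gene_length=900,
        founder_divergence=0.04,
        planted=[
            PlantedFeature(ko="K90001", orthogroup="OGX0001", lineages=(0, 1)),
            PlantedFeature(ko="K90010", orthogroup="OGX0010", lineages=(2,), endosphere=False),
        ],
        n_private_genes=2,
        n_deleted_genes=3,
    )
    return build_community(cfg, seed=42)


@pytest.fixture(scope="session")
def small_design():
    return make_design(3, 3)


@pytest.fixture(scope="session")
def small_readsets(small_community, small_design):
    model = AbundanceModel(depth=4000, error_rate=0.0, host_read_fraction=0.2)
    host = generate_host_decoy(40_000, 0.6, seed=99)
    readsets, abund = simulate_reads(small_community, small_design, model, seed=11, host_seq=host)
    return readsets, abund, host, model
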