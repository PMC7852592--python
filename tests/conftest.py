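"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pytest

import penblup as pb
from penblup.simulate import PopulationDesign, ScenarioConfig, build_dataset, simulate_genome


@pytest.fixture(scope="session")
def tiny_design():
    """A miniature nucleus: 24 litters x 4 generations, records in 2-4."""
    return PopulationDesign(
        n_historical=60,
        historical_generations=10,
        n_base_sires=6,
        n_base_dams=12,
        n_sires=4,
        n_litters=24,
        n_generations=4,
        recorded_generations=(2, 3, 4),
        validation_generation=4,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_design):
    rng = np.random.default_rng(101)
    gmap = pb.GenomeMap.random(n_chromosomes=3, n_markers=40, n_qtl=15, rng=rng)
    return simulate_genome(tiny_design, rng, gmap=gmap)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_design, tiny_sim):
    rng = np.random.default_rng(202)
    cfg = ScenarioConfig(grouping="S12_L2x3", seed=0)
    return build_dataset(tiny_sim, cfg, rng, design=tiny_design)


@pytest.fixture(scope="session")
def micro_pedigree():
    """Hand-built 6-animal pedigree with a full-sib mating (F = 0.25)."""
    import pandas as pd

    from penblup.pedigree import Pedigree

    df = pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5, 6],
            "sire": [0, 0, 1, 1, 3, 3],
            "dam": [0, 0, 2, 2, 4, 4],
            "generation": [0, 0, 1, 1, 2, 2],
        }
    )
    return Pedigree.from_dataframe(df)
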