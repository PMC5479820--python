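import numpy as np
import pytest

from hybrase import (PipelineConfig, PlantedSet, ScenarioConfig, run_all,
                     simulate_dataset)
from hybrase.data import CHROMOSOME, GenomePair, Replicon


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pair(seq_v: str, seq_m: str, name: str = "chr") -> GenomePair:
    """Two single-chromosome genomes from explicit sequences."""
    return GenomePair(
        species=("v", "m"),
        replicons={
            "v": [Replicon(f"v_{name}", seq_v, CHROMOSOME)],
            "m": [Replicon(f"m_{name}", seq_m, CHROMOSOME)],
        })


@pytest.fixture
def toy_scenario_config():
    return ScenarioConfig(
        genome_length=40_000, n_orthologs=60, rng_seed=3,
        planted_set=PlantedSet(n_members=12),
        n_background_categories=3, background_category_size=10)


@pytest.fixture(scope="session")
def toy_run():
    """One small but complete pipeline run, shared across tests."""
    scfg = ScenarioConfig(
        genome_length=40_000, n_orthologs=60, rng_seed=3,
        planted_set=PlantedSet(n_members=12),
        n_background_categories=3, background_category_size=10)
    cfg = PipelineConfig(n_resamples=300, n_permutations=300, min_reads=50,
                         min_category_size=5, rng_seed=3)
    data = simulate_dataset(scfg)
    return data, run_all(data, cfg), cfg
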