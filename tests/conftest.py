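import numpy as np
import pytest

from epiline import synthgen as sg


@pytest.fixture(scope="session")
def small_genome():
    return sg.make_reference(11, {"chr1": 20_000}, 0.36)


@pytest.fixture(scope="session")
def te_sequence():
    return sg.make_reference(12, {"te": 2_000}).sequences["te"]


@pytest.fixture()
def planted(small_genome, te_sequence):
    """A carrier genome with a 7 bp TSD insertion and its truth."""
    ins = sg.PlantedInsertion("chr1", 9_000, te_sequence, tsd_length=7)
    return small_genome, sg.plant_insertion(small_genome, ins), ins


@pytest.fixture(scope="session")
def star_alignment():
    cfg = sg.EvolutionConfig(length=3_000, n_tips=30, age_years=5e5, rate=6.8e-9, seed=21)
    return sg.evolve_star(cfg), cfg


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
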