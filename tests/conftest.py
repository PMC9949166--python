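import logging

import numpy as np
import pytest

from prebioscreen.agent_sim import ArenaConfig
from prebioscreen.model_core import Medium
from prebioscreen.synthetic_data import (
    BenchmarkSpec,
    SpeciesSpec,
    generate_species_model,
    generate_two_species_benchmark,
)

logging.getLogger("prebioscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def benchmark():
    """Default two-species benchmark with planted ground truth."""
    return generate_two_species_benchmark(BenchmarkSpec(seed=1))


@pytest.fixture(scope="session")
def small_arena_config():
    """Down-scaled arena for fast tests (the default grid is 30x30)."""
    return ArenaConfig(grid_shape=(10, 10))


@pytest.fixture()
def simple_species():
    """One species eating two compounds with distinct yields."""
    model = generate_species_model(
        SpeciesSpec(species_id="sp", uptake_compounds={"A": 1.0, "B": 2.0})
    )
    medium = Medium({"A": 10.0, "B": 5.0}, name="simple")
    return model, medium


def random_species_spec(rng: np.random.Generator, idx: int) -> SpeciesSpec:
    """A random valid toy species (bounded size, random yields)."""
    n = int(rng.integers(1, 4))
    compounds = [f"c{idx}_{k}" for k in range(n)]
    yields = {c: float(rng.uniform(0.1, 3.0)) for c in compounds}
    if rng.random() < 0.3:  # sometimes plant a growth-inert compound
        yields[f"c{idx}_x"] = 0.0
    dead = {f"c{idx}_d"} if rng.random() < 0.5 else set()
    return SpeciesSpec(species_id=f"rand{idx}", uptake_compounds=yields,
                       dead_end_compounds=dead)
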