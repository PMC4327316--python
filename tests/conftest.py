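import numpy as np
import pandas as pd
import pytest

from clonemap.plate import make_grid
from clonemap.simulate import (DesignPool, PyroErrorModel, SynthesisErrorModel,
                               gen_pool, populate_plate, sample_abundances,
                               simulate_reads, synthesize_molecules)


@pytest.fixture(scope="session")
def small_pool() -> DesignPool:
    return gen_pool(50, 120, seed=11)


@pytest.fixture(scope="session")
def square22():
    return make_grid(2, 2, 10, "square")


@pytest.fixture(scope="session")
def clean_readset(small_pool):
    """Error-free reads: every read equals its design, identity camera."""
    profile = sample_abundances(small_pool, 1.0, seed=1)
    mols = synthesize_molecules(small_pool, profile,
                                SynthesisErrorModel.error_free(), 400, seed=2)
    grid = make_grid(40, 40, 50, "hex")
    plate = populate_plate(grid, mols, 0.1, seed=3)
    reads = simulate_reads(plate, PyroErrorModel.error_free(), None, seed=4).reads
    return reads, plate, grid
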