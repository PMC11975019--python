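import numpy as np
import pandas as pd
import pytest

from clonemem import simulate


@pytest.fixture(scope="session")
def small_clonal():
    """20 clones x 50 cells with a strong planted clone component."""
    cfg = simulate.SimulationConfig(
        seed=42,
        n_cells=1000,
        n_clones=20,
        n_features=10,
        clone_sd=1.0,
        noise_sd=0.1,
        frac_high_subpop=0.0,
        conditions={"control": 0.0},
    )
    return simulate.simulate_clonal_scores(cfg)


@pytest.fixture(scope="session")
def null_clonal():
    """No planted clone structure at all."""
    cfg = simulate.SimulationConfig(
        seed=43,
        n_cells=400,
        n_clones=20,
        n_features=50,
        clone_sd=0.0,
        noise_sd=1.0,
        frac_heritable=0.0,
        frac_high_subpop=0.0,
        conditions={"control": 0.0},
    )
    return simulate.simulate_clonal_scores(cfg)
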