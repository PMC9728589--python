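import numpy as np
import pytest

import haplovolve as hv
from haplovolve.simulate import SimulationConfig


@pytest.fixture(scope="session")
def toy_grid():
    return hv.default_toy_grid()


@pytest.fixture(scope="session")
def panel_and_base(toy_grid):
    return hv.simulate_founder_panel(toy_grid, seed=1)


@pytest.fixture(scope="session")
def panel(panel_and_base):
    return panel_and_base[0]


@pytest.fixture(scope="session")
def base_table(panel_and_base):
    return panel_and_base[1]


@pytest.fixture(scope="session")
def long_grid():
    # single long chromosome: >2,000 loci for null-calibration checks
    return hv.GenomeGrid(("chrL",), (2_100_000,))


@pytest.fixture(scope="session")
def selected_run(toy_grid, panel_and_base):
    """One treatment with a planted selected locus, with noise, plus base
    as observed (shared by several tests)."""
    _, base = panel_and_base
    cfg = SimulationConfig(
        selected_loci=(("chr02", 150_000),),
        selection_coefficients=(0.05,),
        target_haplotypes=("A5",),
        n_replicates=8,
        seed=11,
    )
    evolved, truth = hv.simulate_evolution(base, cfg)
    noisy = [
        hv.add_measurement_noise(t, 0.01, seed=200 + i)
        for i, t in enumerate(evolved)
    ]
    for i, t in enumerate(noisy):
        t.population = f"drug_{i + 1}"
    base_obs = hv.add_measurement_noise(base, 0.004, seed=199)
    return base, base_obs, noisy, truth
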