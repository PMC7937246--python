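import warnings

import numpy as np
import pytest

from pyroherit.synth import (
    FieldLayout,
    PedigreeConfig,
    SimulationConfig,
    simulate_trial,
)

warnings.filterwarnings("ignore", message=".*missing channels contribute 0.*")
warnings.filterwarnings("ignore", message=".*permutation threshold will be coarse.*")


def tiny_config(seed: int = 3, **overrides) -> SimulationConfig:
    """Small but structurally complete trial: 3x3 factorial + OP + parents,
    3 blocks on a 6x30 grid, 8 trays, 30 standard runs."""
    defaults = dict(
        pedigree=PedigreeConfig(
            n_mothers=3, n_fathers=3, offspring_per_cross=5,
            n_open_pollinated_per_mother=2, include_parents=True,
            total_offspring=None,
        ),
        layout=FieldLayout(n_rows=6, trees_per_row=30, n_blocks=3, survival_rate=0.95),
        n_trays=8, vials_per_tray=48, standard_replicates_total=30,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_trial():
    return simulate_trial(tiny_config())


@pytest.fixture(scope="session")
def study_trial():
    """Full study-scale trial (~1000 genotypes, ~2721 ramets, 125 trays)."""
    return simulate_trial(SimulationConfig(seed=2024))


@pytest.fixture(scope="session")
def grid_30x100():
    """Row/position labels and metric coordinates for the 30 x 100 field."""
    rows, pos = np.meshgrid(np.arange(30), np.arange(100), indexing="ij")
    rows, pos = rows.ravel(), pos.ravel()
    coords = np.column_stack([rows * 3.0, pos * 1.0])
    return rows, pos, coords
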