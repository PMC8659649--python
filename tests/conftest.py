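import numpy as np
import pytest

from tsetse_sdm import (
    GridSpec,
    SyntheticScenario,
    TrapRecord,
    generate_covariates,
    simulate_traps,
    true_suitability,
)


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """Desk-size landscape used by most integration-style tests."""
    return SyntheticScenario(
        grid_shape=(40, 40),
        n_traps=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_stack(small_scenario):
    return generate_covariates(small_scenario)


@pytest.fixture(scope="session")
def small_truth(small_scenario, small_stack):
    return true_suitability(
        small_stack, small_scenario.true_coefficients, small_scenario.protected_effect
    )


@pytest.fixture(scope="session")
def small_records(small_scenario, small_stack, small_truth):
    truths = {"sp1": small_truth, "sp2": small_truth}
    return simulate_traps(small_stack, truths, small_scenario)


@pytest.fixture
def unit_grid() -> GridSpec:
    """10x10 grid of 500 m cells with the north-west corner at (0, 5000)."""
    return GridSpec(x0=0.0, y0=5000.0, cell=500.0, nrows=10, ncols=10)


def make_record(
    trap_id="T1",
    site_id="S1",
    x=100.0,
    y=100.0,
    counts=None,
    trap_days=10,
    vegetation="dense_forest",
    in_protected=False,
    distance=1000.0,
) -> TrapRecord:
    return TrapRecord(
        trap_id=trap_id,
        site_id=site_id,
        x=x,
        y=y,
        species_counts=counts or {"sp1": 0},
        trap_days=trap_days,
        vegetation_class=vegetation,
        in_protected=in_protected,
        distance_to_protected=0.0 if in_protected else distance,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
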