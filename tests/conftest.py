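import numpy as np
import pandas as pd
import pytest

from m6apattern import (
    ExpressionMatrix,
    SimulationConfig,
    Unit,
    load_regulator_registry,
    preset_config,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def registry():
    return load_regulator_registry()


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted cohort (n=150, 3 clusters, shift 2 sigma)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Smaller cohort for cheaper downstream tests."""
    return simulate_cohort(SimulationConfig(seed=5, n_samples=90, n_genes=800, n_signal_genes=30))


@pytest.fixture(scope="session")
def null_cohort():
    return simulate_cohort(preset_config("null", seed=3, n_samples=120))


@pytest.fixture()
def tiny_expr():
    """5 genes x 4 samples deterministic matrix."""
    rng = np.random.default_rng(42)
    vals = pd.DataFrame(
        rng.uniform(1, 100, size=(5, 4)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(4)],
    )
    return ExpressionMatrix(vals, Unit.TPM)
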