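import numpy as np
import pytest

import frailtysim as fs


@pytest.fixture(scope="session")
def truth():
    """A seeded synthetic world with known parameters."""
    return fs.make_truth(fs.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def fixtures():
    return fs.load_fixture_tables()


@pytest.fixture(scope="session")
def england():
    """The calibrated reference baseline (cached across the session)."""
    return fs.calibrate_england_baseline()


@pytest.fixture(scope="session")
def england_outputs(england):
    b = england
    return fs.run_pipeline(b.initial, b.params_fn(), b.entries,
                           b.service_rates, b.unit_costs, 2025, 2040)


def random_parameter_set(seed: int) -> fs.ParameterSet:
    """A valid random rate set, occasionally with outflow sums above 1 so
    the capping path is exercised."""
    rng = np.random.default_rng(seed)
    hi = 0.9 if seed % 5 == 0 else 0.25
    mix = rng.dirichlet(np.ones(4))
    return fs.ParameterSet(
        transition=rng.uniform(0, hi, (4, 3)),
        mortality=rng.uniform(0, hi, (4, 4)),
        ageing=rng.uniform(0, hi, 3),
        entry_mix=mix / mix.sum(),
    )


def random_stocks(seed: int, year: int = 2025) -> fs.StockVector:
    rng = np.random.default_rng(seed + 10_000)
    return fs.StockVector(rng.uniform(0, 2e6, (4, 4)), year)
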