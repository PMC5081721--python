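import numpy as np
import pytest

from tfacea import (SyntheticConfig, default_run_config, generate_inputs)

#: reduced-size generator configuration used by most unit tests
SMALL_SYN = SyntheticConfig(seed=0, max_age=30, population_total=1.0e4)


@pytest.fixture(scope="session")
def small_inputs():
    """Small synthetic input trio (31 ages, 10k persons)."""
    return generate_inputs(SMALL_SYN)


@pytest.fixture(scope="session")
def default_inputs():
    """Full-size default synthetic inputs (EU-like, 508M persons)."""
    return generate_inputs(SyntheticConfig())


@pytest.fixture(scope="session")
def run_cfg():
    """Packaged example run configuration (base case, 85-y horizon)."""
    return default_run_config()


@pytest.fixture(scope="session")
def short_cfg():
    """Example configuration shortened to a 15-y horizon for cheap runs."""
    return default_run_config(horizon_years=15)


def flat_tables(ages, q, p_cad, cf):
    """Build a (LifeTable, MorbidityTable) pair with constant values."""
    from tfacea import LifeTable, MorbidityTable

    ages = np.asarray(ages, dtype=int)
    shape = (len(ages), 2)
    life = LifeTable.from_arrays(ages, q_all_cause=np.full(shape, q))
    morb = MorbidityTable.from_arrays(ages, p_cad_first=np.full(shape, p_cad),
                                      case_fatality=np.full(shape, cf))
    return life, morb
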