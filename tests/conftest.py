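import numpy as np
import pytest

from greydecision.panel import IndicatorSeries
from greydecision.simulate import SimulationConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """Deterministic 3-country, 2-factor, 10-year synthetic panel."""
    config = SimulationConfig(n_countries=3, n_years=10, seed=7)
    return generate_panel(config)


@pytest.fixture()
def toy_series():
    def make(values, country="c1", indicator="x", start_year=2001):
        years = tuple(range(start_year, start_year + len(values)))
        return IndicatorSeries(country, indicator, years, tuple(values))

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
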