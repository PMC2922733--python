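"""Shared synthetic fixtures, generated at collection time (no stored data)."""

import numpy as np
import pytest

from ozoneimpact import exposure, synthetic


@pytest.fixture(scope="session")
def small_network():
    """15-station, 3-community network used across GP tests."""
    stations, communities = synthetic.generate_network(
        n_stations=15, n_communities=3, seed=11)
    return stations, communities


@pytest.fixture(scope="session")
def paper_regime_truth(small_network):
    stations, _ = small_network
    return synthetic.default_truth(sorted(stations["state"].unique()),
                                   seed=11)


@pytest.fixture(scope="session")
def gp_panel(small_network, paper_regime_truth):
    """Complete 15 x 60 summer panel at the observed-regime truth."""
    stations, _ = small_network
    dates = exposure.summer_dates(2000)[:60]
    weather = synthetic.generate_weather(stations, dates, seed=11)
    ozone = synthetic.generate_ozone(stations, weather, paper_regime_truth,
                                     seed=11)
    return synthetic.assemble_panel(stations, weather, ozone)


@pytest.fixture(scope="session")
def health_dataset():
    """3 communities x 14 summers of mortality with known risks."""
    stations, communities = synthetic.generate_network(
        n_stations=8, n_communities=3, seed=21)
    truth = synthetic.default_truth(sorted(stations["state"].unique()),
                                    seed=21)
    dates = [d for y in range(1987, 2001) for d in exposure.summer_dates(y)]
    weather = synthetic.generate_weather(stations, dates, seed=21)
    ozone = synthetic.generate_ozone(stations, weather, truth, seed=21)
    oz_comm = synthetic.community_daily_mean(ozone, stations, communities)
    temp_comm = synthetic.community_daily_mean(weather["temperature"],
                                               stations, communities)
    mortality = synthetic.generate_mortality(communities, oz_comm, temp_comm,
                                             truth, seed=21)
    return mortality, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
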