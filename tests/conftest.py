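import numpy as np
import pytest

from thermopop import demography, projection, weather


@pytest.fixture(scope="session")
def schedule():
    """The package's default D. suzukii-like demographic schedule."""
    return demography.default_schedule()


@pytest.fixture(scope="session")
def hot_summer_weather():
    """One synthetic year whose midsummer mean exceeds the fecundity optimum."""
    return weather.synth_weather(
        start="2013-01-01", n_days=365, seed=42, site="hot-summer",
        **weather.REGION_PRESETS["hot-summer"],
    )


@pytest.fixture(scope="session")
def temperate_weather():
    """One synthetic year that never exceeds the fecundity optimum."""
    return weather.synth_weather(
        start="2013-01-01", n_days=365, seed=42, site="temperate",
        **weather.REGION_PRESETS["temperate"],
    )


def constant_weather(t: float, n_days: int = 201, start: str = "2013-01-01"):
    """Noise-free constant-temperature series (tmin = tmax = tmean = t)."""
    return weather.synth_weather(t, 0.0, 0.0, 0.0, start, n_days, seed=0)


@pytest.fixture(scope="session")
def shift_schedule():
    """Survival 1 everywhere, fecundity 0: the pure age-advance matrix."""
    one = demography.ThermalPerformanceCurve(
        "quadratic", (1.0, 0.0, 0.0), domain=(-50.0, 60.0)
    )
    zero_weights = np.zeros(50)
    return demography.DemographicSchedule(
        {(1, 50): one}, zero_weights, one, max_age=50
    )
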