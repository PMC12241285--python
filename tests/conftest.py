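import numpy as np
import pytest

from voltiscan.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full-length synthetic data set under the default study conditions."""
    cfg = SyntheticConfig(seed=7)
    temps, catches, truth = generate_dataset(cfg)
    return cfg, temps, catches, truth


@pytest.fixture(scope="session")
def strong_signal_dataset():
    """50 study years with a steep temperature response, for recovery tests."""
    cfg = SyntheticConfig(seed=11, year_range=(1968, 2017),
                          logistic_beta=6.0, logistic_alpha=-60.0)
    temps, catches, truth = generate_dataset(cfg)
    return cfg, temps, catches, truth


@pytest.fixture(scope="session")
def classified_default(default_dataset):
    """Mixture fit and year classification of the default data set."""
    from voltiscan.flight_periods import classify_years, fit_mixture, weekly_observations

    cfg, temps, catches, truth = default_dataset
    obs = weekly_observations(catches)
    fit = fit_mixture(obs["week"].to_numpy(), seed=0)
    status = classify_years(catches, fit,
                            years=range(cfg.year_range[0], cfg.year_range[1] + 1))
    return fit, status
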