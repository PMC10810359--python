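import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fertcount as fc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def zip_population():
    """Small ZIP population with the default (survey-style) coefficients."""
    cfg = fc.SyntheticConfig(n_women=400, family="zip", seed=20240)
    return fc.generate_population(cfg), cfg


@pytest.fixture(scope="session")
def person_year_table(zip_population):
    pop, cfg = zip_population
    return fc.build_person_year_table(
        pop.women, pop.births, cfg.window_months, covariates=pop.design
    )


@pytest.fixture(scope="session")
def toy_design():
    """2000 x 3 design (intercept, continuous, dummy) for model fits."""
    rng = np.random.default_rng(101)
    n = 2000
    return pd.DataFrame(
        {
            "Intercept": np.ones(n),
            "x1": rng.normal(size=n),
            "x2": rng.binomial(1, 0.4, n).astype(float),
        }
    )


@pytest.fixture(scope="session")
def zip_counts(toy_design):
    """ZIP response on toy_design with known (beta, gamma)."""
    from scipy.special import expit

    rng = np.random.default_rng(202)
    beta = np.array([0.2, 0.3, -0.4])
    gamma = np.array([-1.0, 0.5, 0.0])
    X = toy_design.to_numpy()
    mu = np.exp(X @ beta)
    theta = expit(X @ gamma)
    y = np.where(rng.random(len(X)) < theta, 0, rng.poisson(mu))
    return y, beta, gamma
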