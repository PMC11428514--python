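import numpy as np
import pandas as pd
import pytest

import habsuit as hb


@pytest.fixture(scope="session")
def survey_grid():
    return hb.make_grid((27.0, 34.0), (122.0, 127.0), 0.5)


@pytest.fixture(scope="session")
def smooth_field():
    """A smooth synthetic suitability field over the survey box."""

    def f(lat, lon):
        lat, lon = np.asarray(lat), np.asarray(lon)
        return 0.5 + 0.4 * np.sin((lat - 27) / 7 * np.pi) * np.cos((lon - 122) / 5 * np.pi)

    return f


def gaussian_survey(mu=20.0, sigma=3.0, q_max=5000.0, n=200, noise_sigma=0.3, seed=0,
                    x_range=(10.0, 30.0)):
    """Stations with a single informative temperature response; salinity and
    depth are independent nuisance covariates."""
    rng = np.random.default_rng(seed)
    env = pd.DataFrame(
        {
            "temp_c": rng.uniform(*x_range, n),
            "sal_psu": rng.uniform(28, 35, n),
            "depth_m": rng.uniform(20, 160, n),
        }
    )
    y = q_max * np.exp(-(((env["temp_c"] - mu) / sigma) ** 2))
    if noise_sigma > 0:
        y = y * np.exp(rng.normal(0.0, noise_sigma, n))
    return env, y.to_numpy()


@pytest.fixture(scope="session")
def default_survey():
    catch, env, truth = hb.generate_survey(hb.default_scenarios(seed=42))
    return catch, env, truth
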