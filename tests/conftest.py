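import numpy as np
import pandas as pd
import pytest

from batemerge.config import SiteConfig, TrueModel, default_sites
from batemerge.weather import simulate_weather


@pytest.fixture(scope="session")
def sites():
    return default_sites()


@pytest.fixture(scope="session")
def two_sites(sites):
    return sites[:2]


@pytest.fixture(scope="session")
def weather_small(two_sites):
    """10 days of hourly weather for two sites."""
    return simulate_weather(two_sites, "2016-01-01", 10, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def glm_frame():
    """A linear-only Poisson frame with known coefficients."""
    rng = np.random.default_rng(7)
    n = 2000
    frame = pd.DataFrame({
        "site_id": rng.choice(["A", "B", "C"], n),
        "T_S": rng.normal(4, 3, n),
        "T_A": rng.normal(8, 5, n),
        "AP": 1013 + rng.normal(0, 8, n),
        "APT": rng.normal(0, 1.5, n),
        "WS": np.abs(rng.normal(3, 2, n)),
        "PR": rng.exponential(0.4, n) * (rng.random(n) < 0.2),
        "CC": rng.integers(0, 9, n).astype(float),
    })
    eta = (-0.5 + 0.08 * frame.T_A - 0.08 * frame.WS
           + 0.01 * (frame.AP - 1013) + 0.4 * (frame.site_id == "B"))
    frame["y"] = rng.poisson(np.exp(eta)).astype(float)
    return frame


@pytest.fixture(scope="session")
def smooth_fit():
    """A GAPM fitted to a simulated frame with known smooth and linear truth."""
    from batemerge.config import species_truth
    from batemerge.experiments import LEAN_SPEC
    from batemerge.gapm import fit_gapm
    from batemerge.simulate import simulate_model_frame

    truth = species_truth("M_myotis")
    frame = simulate_model_frame(truth, 8000, seed=99)
    fit = fit_gapm(frame, LEAN_SPEC, species="M_myotis")
    return truth, frame, fit
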