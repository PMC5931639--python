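import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy.special import expit

import streetshare as ss

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_beta_data(seed, n=30, beta=(-2.0, 0.3), phi=50.0, x_scale=5.0):
    """Simulated beta-regression dataset with known truth."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, x_scale, size=n)
    mu = expit(beta[0] + beta[1] * x)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    y = np.clip(y, 1e-6, 1 - 1e-6)
    return pd.DataFrame({"y": y, "x": x})


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by read-only tests."""
    cfg = ss.GeneratorConfig(
        n_cities=12,
        link_floor=450,
        plan=ss.SamplingPlan(stage2_n=400, target_locations=200),
    )
    return ss.generate_world(cfg, seed=11)


@pytest.fixture(scope="session")
def small_features(small_world):
    return ss.build_feature_table(small_world.annotations)
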