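import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from forestdiv import plot_data, synthetic_data

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def survey():
    """One seeded default two-belt survey shared across tests."""
    stems, plots, truth = synthetic_data.gen_survey(seed=42)
    return stems, plots, truth


@pytest.fixture(scope="session")
def belt_counts(survey):
    """Pooled abundance vectors per belt from the shared survey."""
    stems, _, _ = survey
    out = {}
    for belt in (plot_data.BIRCH, plot_data.PINEOAK):
        table = plot_data.abundance_table([s for s in stems if s.belt == belt], group_by="belt")
        out[belt] = table.pooled_vector()
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
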