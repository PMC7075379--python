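import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import radbioqa as rb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    # the fixtures used inside @given tests are immutable parameter sets,
    # so reuse across generated inputs is safe
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def schedule():
    return rb.FractionSchedule(25)


@pytest.fixture
def tumor_params():
    return rb.ResponseParams("PTV", "tumor", d50=55.0, gamma_slope=2.5, alpha_beta=10.0)


@pytest.fixture
def normal_params():
    return rb.ResponseParams(
        "Rectum", "normal", d50=80.0, gamma_slope=2.2, alpha_beta=3.0, seriality=0.7
    )


def random_differential_dvh(rng: np.random.Generator, n_bins: int, d_lo=5.0, d_hi=90.0):
    """Random valid differential DVH used by oracle-equivalence tests."""
    doses = np.sort(rng.uniform(d_lo, d_hi, n_bins))
    doses += np.arange(n_bins) * 1e-9  # enforce strict increase
    vols = rng.dirichlet(np.ones(n_bins))
    return rb.DVH("random", "differential", doses, vols)
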