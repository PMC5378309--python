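import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cbatt import DesignSpec, scenario_from_table_row

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def ad1_design():
    """The simulation study's reference design: S1 = S2 = 50, t1 = 0.5."""
    return DesignSpec(s1=50, s2=50, t1=0.5, rho=0.4, alpha=0.05, variant="AD1")


@pytest.fixture
def scenario_d6_t05():
    """Biomarker-effect scenario: slope 6, true threshold 0.5."""
    return scenario_from_table_row(6.0, "T", 0.5, 0.40)
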