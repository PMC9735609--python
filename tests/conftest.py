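import pytest
from hypothesis import HealthCheck, settings

from imprintcall import SimConfig, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A 60-gene study with all truth classes represented, shared read-only."""
    config = SimConfig(
        n_genes=60,
        frac_meg=0.15,
        frac_peg=0.15,
        frac_untestable=0.1,
        depth_mean=150.0,
        seed=11,
    )
    return simulate_study(config)
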