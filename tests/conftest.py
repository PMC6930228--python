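import pytest
from hypothesis import HealthCheck, settings

from smmipkit import mipsim

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_reference() -> str:
    return mipsim.build_reference(4000, seed=11)


@pytest.fixture(scope="session")
def toy_panel(toy_reference):
    """Six probes (alternating strands) tiling the toy reference."""
    return mipsim.design_toy_panel(toy_reference, n_probes=6)


@pytest.fixture(scope="session")
def clean_sample(toy_reference, toy_panel):
    """A simulated sample with zero sequencing error and known truth."""
    cfg = mipsim.SimulationConfig(
        seed=3, n_molecules_per_probe=25, pcr_duplication_mean=2.0, seq_error_rate=0.0
    )
    return mipsim.simulate_capture(toy_reference, toy_panel, cfg)
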