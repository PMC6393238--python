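import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def default_params():
    from editscreen.reporter_model import ReporterParams

    return ReporterParams()


@pytest.fixture
def quiet_noise():
    """Deterministic, noise-free measurement model."""
    from editscreen.synth_screen import NoiseConfig

    return NoiseConfig(cv_ffl=0.0, cv_nluc=0.0, seed=0)


@pytest.fixture
def small_inactive_screen(default_params, quiet_noise):
    """One noiseless plate where every compound is inactive."""
    from editscreen.reporter_model import Action
    from editscreen.synth_screen import LibrarySpec, simulate_screen

    lib = LibrarySpec(n_compounds=352, frac_by_action={Action.INACTIVE: 1.0})
    return simulate_screen(default_params, lib, quiet_noise)
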