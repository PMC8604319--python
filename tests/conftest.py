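import pytest
import yaml
from hypothesis import HealthCheck, settings

from harvestmse.cli import _TINY_FACTORIAL_CONFIG, _ZERO_VARIABILITY_CONFIG
from harvestmse.config import (
    EnvironmentalContext,
    SpeciesProfile,
    StartScenario,
    Variability,
    default_config,
    parse_config,
)

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_species(**overrides) -> SpeciesProfile:
    """A small test species (moderate size 600) with optional overrides."""
    kwargs = dict(
        name="testspecies",
        r_mean=0.3,
        K=1200,
        threshold_quasi_extinct=100,
        threshold_low=400,
        threshold_high=800,
        threshold_overabundant=1200,
        sd_r_low=0.05,
        sd_r_high=0.15,
        sd_m_low=0.05,
        sd_m_high=0.15,
        sd_q_low=0.05,
        sd_q_high=0.15,
        sd_h_low=0.05,
        sd_h_high=0.15,
    )
    kwargs.update(overrides)
    return SpeciesProfile(**kwargs)


def make_context(
    species: SpeciesProfile,
    variability: Variability = Variability.LOW,
    start: StartScenario = StartScenario.MODERATE,
) -> EnvironmentalContext:
    return EnvironmentalContext(species, variability, start)


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture()
def zero_var_config():
    """Single-species config with all variation magnitudes zero."""
    return parse_config(yaml.safe_load(_ZERO_VARIABILITY_CONFIG), source="zero_variability")


@pytest.fixture()
def tiny_config():
    """1 species x 2 variability x 1 start, 2 strategies x 3 params, 2 sets."""
    return parse_config(yaml.safe_load(_TINY_FACTORIAL_CONFIG), source="tiny_factorial")
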