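import pytest

from itnevo import ModelParameters


@pytest.fixture
def defaults() -> ModelParameters:
    """Typical field-derived parameter set; per-cycle mortality derived
    exactly from mu and gt (0.271)."""
    return ModelParameters()


@pytest.fixture
def printed(defaults) -> ModelParameters:
    """Same set but with the rounded published per-cycle mortality 0.27,
    used by the worked numerical examples."""
    return defaults.replace(mu_gt=0.27)
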