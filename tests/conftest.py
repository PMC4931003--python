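import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermoreg import (
    EraGeneratorConfig,
    MicrohabitatGeneratorConfig,
    PreferredRange,
    generate_field_records,
    generate_operative_series,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reported_ptr() -> PreferredRange:
    """The set-point interval reported for the study population."""
    return PreferredRange(31.18, 32.50)


@pytest.fixture(scope="session")
def era_records():
    """One draw of both eras from the calibrated generator defaults."""
    recs_a = generate_field_records(EraGeneratorConfig.era_1980s(), seed=101)
    recs_b = generate_field_records(EraGeneratorConfig.era_2012(), seed=202)
    return recs_a, recs_b


@pytest.fixture(scope="session")
def operative_records():
    """One draw of the nine-microhabitat logger series (defaults)."""
    return generate_operative_series(MicrohabitatGeneratorConfig(), seed=303)
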