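import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hbbtyper.allele_catalog import default_catalog
from hbbtyper.reference_model import bundled_locus


@pytest.fixture(scope="session")
def model():
    return bundled_locus()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()
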