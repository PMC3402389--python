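import pytest
from hypothesis import HealthCheck, settings

from genemeta import load_mdm2_studies

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mdm2():
    """The packaged 11-study MDM2 SNP309 lung-cancer dataset."""
    return load_mdm2_studies()
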