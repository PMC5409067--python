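import pytest
from hypothesis import HealthCheck, settings

from amplihap import simdata

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref():
    """The packaged synthetic amplicon reference (1033 bp, 226-codon CDS)."""
    return simdata.build_reference()
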