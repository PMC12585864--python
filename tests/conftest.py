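import pytest
from hypothesis import HealthCheck, settings

import enameliso as ei

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def profiles():
    """The four bundled specimen profiles, in table order."""
    return ei.read_serial_table(ei.bundled_serial_table_path())


@pytest.fixture(scope="session")
def juvenile(profiles):
    return profiles[0]  # NTUM-VP 210127


@pytest.fixture(scope="session")
def subadult(profiles):
    return profiles[1]  # NTUM-VP 230921


@pytest.fixture(scope="session")
def adult(profiles):
    return profiles[2]  # NTUM-VP 230920


@pytest.fixture(scope="session")
def modern(profiles):
    return profiles[3]  # N-000033/NF002445, extant Elephas maximus


@pytest.fixture(scope="session")
def fossil_profiles(profiles):
    return [p for p in profiles if p.epoch != "modern"]
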