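import pytest

from puretone import calibrate, core
from puretone.signal import DeviceProfile


@pytest.fixture(scope="session")
def retspl_tables():
    return core.packaged_retspl_tables()


@pytest.fixture(scope="session")
def er3a(retspl_tables):
    return retspl_tables["ER-3A"]


@pytest.fixture(scope="session")
def device_table():
    return calibrate.packaged_device_output_table()


@pytest.fixture(scope="session")
def xr_profile(device_table):
    return DeviceProfile.from_output_table(device_table, "iPhone XR")
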