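import logging

import pytest

import thermogait as tg

logging.getLogger("thermogait").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sessions6():
    """The default six-session treadmill fixture (seed 0, 2% voltage noise)."""
    return tg.generate_sessions(tg.ProtocolConfig(seed=0))


@pytest.fixture(scope="session")
def features6(sessions6):
    return [tg.extract_features(rec) for rec in sessions6]


@pytest.fixture(scope="session")
def calib6(sessions6):
    """Pooled four-channel calibration fitted on the default fixture."""
    models, reports = tg.calibrate_all(sessions6)
    return models, reports


@pytest.fixture(scope="session")
def noiseless_session():
    quiet = tg.NoiseConfig(voltage_rel_sd=0.0, accel_sd=0.05, strain_sd=0.0)
    return tg.generate_session(tg.ProtocolConfig(seed=3), noise=quiet)
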