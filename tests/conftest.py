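from hypothesis import HealthCheck, settings

import pytest

from matalert import Interval, PatientContext, VitalObservation, default_thresholds

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def thresholds():
    return default_thresholds()


@pytest.fixture
def empty_ctx():
    return PatientContext.empty("p1", "r1")


@pytest.fixture
def postpartum_ctx():
    """Delivered 60 min before t=0 of the observation window (t in minutes)."""
    return PatientContext(
        patient_id="p1", room_id="r1",
        labor_stages=(("delivered", Interval(-60, 24 * 60)),),
        delivery_time_min=-60)


def obs(parameter, value, t=0, pid="p1", room="r1", source="monitor"):
    return VitalObservation(patient_id=pid, room_id=room, time_min=t,
                            parameter=parameter, value=value, source=source)


@pytest.fixture
def make_obs():
    return obs
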