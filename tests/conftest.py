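import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cascnet.sim import SimConfig, SubjectRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_patient(sid, months, age=50.0, sex="M", education=12.0, tiv=1450.0):
    return SubjectRecord(
        subject_id=sid,
        group="patient",
        age=age,
        sex=sex,
        education=education,
        tiv=tiv,
        months_post_rt=months,
    )


@pytest.fixture
def patients():
    """Ten patients with irregular post-RT times."""
    times = [0.5, 2.0, 3.5, 7.0, 12.0, 17.2, 24.0, 40.0, 60.0, 108.0]
    sexes = ["M", "M", "F", "M", "M", "F", "M", "M", "M", "F"]
    return [
        make_patient(f"P{i:03d}", t, age=35.0 + i, sex=s, education=9.0 + i % 8)
        for i, (t, s) in enumerate(zip(times, sexes), start=1)
    ]


@pytest.fixture
def small_sim_config():
    return SimConfig(
        n_patients=20,
        n_controls=10,
        roi_names=("A", "B", "C"),
        noise_sd=0.3,
        rng_seed=7,
    )
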