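import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import icloco as ic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> ic.AnalysisConfig:
    return ic.AnalysisConfig()


@pytest.fixture(scope="session")
def demo_session() -> ic.SessionBundle:
    """Small all-signal synthetic session shared across tests."""
    return ic.build_paper_matched_session("demo", seed=123)


@pytest.fixture(scope="session")
def demo_segmentation(demo_session, cfg):
    speed = ic.compute_speed(demo_session.signals["speed"], cfg)
    periods = ic.walking_periods(speed, cfg)
    labels = ic.label_segments(speed.duration, periods, cfg)
    onsets = ic.detect_treadmill_onsets(demo_session.signals["treadmill_sensor"], cfg)
    return speed, periods, labels, onsets


def make_signal(samples, rate=1000.0, units="a.u.", t0=0.0) -> ic.ContinuousSignal:
    return ic.ContinuousSignal(np.asarray(samples, dtype=float), rate, units=units, t0=t0)
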