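import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("hrval", database=None, deadline=None)
settings.load_profile("hrval")

from hrval import (
    ActivitySpec,
    CleaningConfig,
    HRSeries,
    ProtocolSpec,
    SubjectParams,
    default_protocol,
)


@pytest.fixture
def cfg():
    return CleaningConfig()


@pytest.fixture
def proto():
    return default_protocol()


@pytest.fixture
def tiny_proto():
    """Short two-activity protocol for fast end-to-end tests."""
    return ProtocolSpec(activities=(
        ActivitySpec("lying", 60, 0.0, 0.0),
        ActivitySpec("jogging", 80, 0.5, 0.6),
    ), rest_between_s=20)


@pytest.fixture
def subject():
    return SubjectParams("S01")


@pytest.fixture
def make_series():
    """Factory for hand-built HRSeries."""

    def _make(hr, activity="walking", t=None, subject_id="S01", device_id="dev",
              position="upper_arm", session=1):
        hr = np.asarray(hr, dtype=float)
        if t is None:
            t = np.arange(len(hr))
        if np.isscalar(activity) or isinstance(activity, str):
            activity = [activity] * len(hr)
        return HRSeries(subject_id, device_id, position, session,
                        pd.DataFrame({"t_s": np.asarray(t, dtype=int),
                                      "activity": list(activity),
                                      "hr_bpm": hr}))

    return _make


@pytest.fixture
def make_windows():
    """Factory for tidy windowed-pair tables."""

    def _make(d, reference=100.0, subject_id="S01", session=1,
              position="upper_arm", activity="walking"):
        d = np.asarray(d, dtype=float)
        ref = np.broadcast_to(np.asarray(reference, dtype=float), d.shape)
        return pd.DataFrame({
            "subject_id": subject_id, "session": session, "position": position,
            "activity": activity, "t_s": np.arange(len(d)) * 10,
            "hr_device": ref + d, "hr_reference": ref, "n": 10,
        })

    return _make
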