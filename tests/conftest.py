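import numpy as np
import pytest

from kinedecode.mocap_io import MarkerRecording, default_marker_joint_map
from kinedecode.pipeline import FeatureOptions, features_from_recordings
from kinedecode.synthetic_data import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def jmap():
    return default_marker_joint_map()


@pytest.fixture
def simple_recording():
    """One marker moving linearly over 5 frames at 100 Hz."""
    positions = np.arange(15, dtype=float).reshape(5, 1, 3)
    return MarkerRecording(
        participant_id="P000",
        stimulus_id="S00",
        marker_labels=["m0"],
        positions=positions,
        sampling_rate=100.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but fully structured cohort reused by read-only tests."""
    spec = SyntheticCohortSpec(n_dancers=8, n_stimuli=2, duration=5.0, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return features_from_recordings(
        tiny_cohort.recordings.values(),
        tiny_cohort.marker_joint_map,
        FeatureOptions(),
    )


def synthetic_marker_recording(seed=0, n_frames=100, rate=60.0):
    """Random-walk style recording over the full default 21-marker layout."""
    from kinedecode.synthetic_data import _SKELETON

    rng = np.random.default_rng(seed)
    markers = list(_SKELETON)
    rest = np.array([_SKELETON[m] for m in markers])
    t = np.arange(n_frames) / rate
    positions = rest[None, :, :] + 50.0 * np.sin(
        2 * np.pi * rng.uniform(0.5, 3.0, size=(1, len(markers), 3)) * t[:, None, None]
        + rng.uniform(0, 2 * np.pi, size=(1, len(markers), 3))
    )
    return MarkerRecording(
        participant_id="P000",
        stimulus_id="S00",
        marker_labels=markers,
        positions=positions,
        sampling_rate=rate,
    )
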