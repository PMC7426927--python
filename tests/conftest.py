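import numpy as np
import pytest

from slowmod import Level, LevelSchedule, SessionRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_recording(
    data: np.ndarray,
    fs: float = 200.0,
    levels=None,
    loc=None,
    positions=None,
    mask=None,
) -> SessionRecording:
    """Minimal recording wrapper used across the unit tests."""
    data = np.atleast_2d(data)
    n_ch, n = data.shape
    if levels is None:
        levels = [Level("all", 0.0, n / fs, 0.0)]
    if positions is None:
        # distinct points on a line offset into 3-D
        positions = np.column_stack(
            [np.linspace(-1, 1, n_ch), np.zeros(n_ch), np.ones(n_ch)]
        )
    return SessionRecording(
        data=data,
        sample_rate_hz=fs,
        channel_labels=[f"CH{i:02d}" for i in range(n_ch)],
        channel_positions=positions,
        schedule=LevelSchedule(list(levels), loc_time_s=loc),
        artifact_mask=mask,
    )


@pytest.fixture
def make_rec():
    return make_recording
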