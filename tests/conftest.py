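import numpy as np
import pytest

from stairclust.ingest import LabelTrack, Recording
from stairclust.synthetic_data import (
    EmbeddingSpec,
    SignalSpec,
    default_schedule,
    gen_recording,
)


@pytest.fixture
def flat_recording():
    """Two minutes of synthetic flat walking at 20 Hz."""
    rec, track = gen_recording(SignalSpec(schedule=[("flat", 120.0)], seed=11))
    return rec, track


@pytest.fixture
def mixed_recording():
    """Short mixed-activity recording (flat + stairs)."""
    spec = SignalSpec(
        schedule=[("flat", 240.0), ("upstairs", 40.0), ("flat", 240.0), ("downstairs", 40.0)],
        seed=7,
    )
    return gen_recording(spec)


@pytest.fixture
def sine_recording():
    """Pure 1 Hz unit sinusoid on all axes, 30 s at 20 Hz."""
    t = np.arange(600) / 20.0
    sig = np.sin(2 * np.pi * 1.0 * t)
    return Recording(
        subject_id="sine",
        t=t,
        accel=np.column_stack([sig, sig, sig]),
        sampling_rate=20.0,
    )


@pytest.fixture
def hypothesis_geometry_spec():
    """Embedding geometry consistent with the three stair hypotheses."""
    return EmbeddingSpec(
        n_total=1000,
        stair_fraction=0.05,
        walk_center=(0.0, 0.0),
        stair_center=(30.0, 0.0),
        walk_spread=5.0,
        stair_spread=1.0,
        extraneous=[((0.0, 15.0), 2.0, 30), ((-12.0, -8.0), 2.5, 25)],
        seed=42,
    )


def write_csvs(tmp_path, rec: Recording, track: LabelTrack):
    from stairclust.synthetic_data import write_fixture_csvs

    rec_path = tmp_path / "recording.csv"
    lab_path = tmp_path / "labels.csv"
    write_fixture_csvs(rec, track, rec_path, lab_path)
    return rec_path, lab_path
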