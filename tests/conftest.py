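import numpy as np
import pytest

from hprw import AcquisitionSpec, Track


@pytest.fixture
def acq() -> AcquisitionSpec:
    return AcquisitionSpec(frame_interval=0.5)


def make_track(frames, positions, track_id="t0", condition=None) -> Track:
    return Track(
        track_id=track_id,
        frames=np.asarray(frames),
        positions=np.asarray(positions, dtype=float),
        condition=condition or {},
    )


def random_gapped_track(rng: np.random.Generator, n_slots: int = 50, gap_p: float = 0.15,
                        track_id: str = "r0") -> Track:
    """A random-walk track with random interior gaps (endpoints kept)."""
    keep = rng.random(n_slots) >= gap_p
    keep[0] = keep[-1] = True
    frames = np.flatnonzero(keep)
    positions = np.cumsum(rng.normal(0, 1.0, size=(n_slots, 3)), axis=0)[keep]
    return make_track(frames, positions, track_id=track_id)
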