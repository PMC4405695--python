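import numpy as np
import pytest

from vesitrack.tracks import Track


def make_track(xs, ys=None, frame_interval=1.0, frames=None, tid="t"):
    """Build a Track from coordinate lists (µm)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.zeros_like(xs) if ys is None else np.asarray(ys, dtype=float)
    if frames is None:
        frames = np.arange(len(xs))
    return Track(track_id=tid, frames=np.asarray(frames),
                 positions=np.column_stack([xs, ys]),
                 frame_interval=frame_interval)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
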