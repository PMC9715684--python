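import numpy as np
import pytest

from ttmkit.words import FrameStructure


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_frame(rng, n_channels: int = 25) -> FrameStructure:
    n_hits = int(rng.integers(0, 5))
    chans = rng.choice(n_channels, size=n_hits, replace=False)
    hits = {int(c): (int(rng.integers(0, 256)), True) for c in chans}
    return FrameStructure(
        step=int(rng.integers(0, 1 << 16)),
        stop_code=int(rng.integers(0, 256)),
        sync_valid=bool(rng.integers(0, 2)),
        ref_pixel=bool(rng.integers(0, 2)),
        ref_line=bool(rng.integers(0, 2)),
        ref_frame=bool(rng.integers(0, 2)),
        spare=int(rng.integers(0, 256)),
        hits=hits,
    )


@pytest.fixture
def frame_factory():
    return random_frame
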