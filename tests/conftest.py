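import numpy as np
import pytest

from dyadmotion.segmentation import MovementSegmentList


def random_segments(rng: np.random.Generator, window=(0.0, 300.0), mean_n=8,
                    min_dur=0.05, max_dur=20.0) -> np.ndarray:
    """Random sorted disjoint half-open intervals inside ``window`` (may be
    shorter than the 350 ms cleaning floor — useful as raw input)."""
    t0, t1 = window
    n = rng.poisson(mean_n)
    segs = []
    t = t0
    for _ in range(n):
        t += rng.uniform(0.01, (t1 - t0) / max(mean_n, 1))
        dur = rng.uniform(min_dur, max_dur)
        if t + dur >= t1:
            break
        segs.append([t, t + dur])
        t += dur
    return np.array(segs).reshape(-1, 2)


def make_list(segs, role="infant", body_part="arms", window=(0.0, 300.0)) -> MovementSegmentList:
    return MovementSegmentList(role=role, body_part=body_part, window=window, segments=segs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
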