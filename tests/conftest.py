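import numpy as np
import pytest

from kmipd import DigitizedCurve, IPDataset

# Raw extracted coordinates of the worked example curve: the first click
# lands at a slightly negative time, as trace-based digitizers produce.
TABLE2_RAW = [
    (-1.401, 0.998984),
    (3.11735, 0.995015),
    (3.87041, 0.994519),
    (4.62347, 0.994519),
    (5.37653, 0.994519),
]


@pytest.fixture
def table2_curve() -> DigitizedCurve:
    t, s = zip(*TABLE2_RAW)
    return DigitizedCurve(np.array(t), np.array(s))


def make_small_ipd(seed: int, n: int, cens_frac: float = 0.2) -> IPDataset:
    """A small single-arm dataset with distinct event times."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(10.0, n)
    t = np.round(t, 2) + np.arange(n) * 1e-3  # force distinct times
    event = (rng.random(n) > cens_frac).astype(int)
    if event.sum() == 0:
        event[0] = 1
    return IPDataset(t, event, np.zeros(n, int))
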