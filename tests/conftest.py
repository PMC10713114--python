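import numpy as np
import pytest

from cytopipe import ChannelInfo, Dataset, Sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sample(events, sample_id="S1", group="g", labels=None, **kw):
    events = np.asarray(events, dtype=np.float64)
    labels = labels or [f"FL{i + 1}" for i in range(events.shape[1])]
    channels = [
        ChannelInfo(short_name=l, label=l, role="fluorescence", index=i + 1)
        for i, l in enumerate(labels)
    ]
    return Sample(sample_id=sample_id, events=events, channels=channels, group=group, **kw)


@pytest.fixture
def two_sample_dataset(rng):
    """Two small samples over two channels with bimodal structure."""
    def draw(shift):
        low = rng.normal(1.0 + shift, 0.15, size=(600, 2))
        high = rng.normal(3.0 + shift, 0.15, size=(400, 2))
        return np.vstack([low, high])

    s1 = make_sample(draw(0.0), "A", "g1")
    s2 = make_sample(draw(0.4), "B", "g2")
    return Dataset([s1, s2], {"A": "g1", "B": "g2"})
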