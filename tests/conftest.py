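import numpy as np
import pytest

from stopem import ChannelPair, StopCountTrack, TranscriptRef


@pytest.fixture
def transcript():
    return TranscriptRef(name="toy", sequence="ACGTACGTAC")


def make_pair(d_t, n_t, d_c, n_c, name="toy_pair"):
    L = len(d_t)
    tr = TranscriptRef(name="t", sequence="ACGT" * (L // 4 + 1))
    tr = TranscriptRef(name="t", sequence=tr.sequence[:L])
    return ChannelPair(
        treated=StopCountTrack(tr, np.asarray(d_t), np.asarray(n_t), channel="treated"),
        control=StopCountTrack(tr, np.asarray(d_c), np.asarray(n_c), channel="control"),
        sample_name=name,
    )


@pytest.fixture
def toy_pair():
    # five positions: quiet background, strong stop both channels,
    # treated-only spike, low coverage, zero coverage
    return make_pair(
        d_t=[1, 40, 30, 0, 0],
        n_t=[500, 480, 510, 5, 0],
        d_c=[2, 38, 1, 0, 0],
        n_c=[490, 500, 505, 4, 10],
    )
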