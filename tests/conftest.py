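import numpy as np
import pandas as pd
import pytest

from lagcoder.containers import Recording, WordTable


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def word_table():
    return WordTable(pd.DataFrame({
        "word": ["the", "old", "man"],
        "onset_s": [0.50, 1.00, 2.00],
        "offset_s": [0.75, 1.50, 2.40],
        "surprisal": [3.0, 5.0, 1.5],
        "token_count": [1, 1, 1],
    }))


@pytest.fixture()
def eeg_512hz(rng):
    """Ten seconds of 512 Hz white noise on 4 scalp + 2 mastoid channels."""
    data = rng.standard_normal((5120, 6))
    labels = ["A1", "A2", "A3", "A4", "M1", "M2"]
    return Recording("run00", data, 512.0, labels, ["M1", "M2"])
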