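import numpy as np
import pytest

from ptpscout.sequence_library import PeptideWindow, ProteinRecord
from ptpscout.synthetic_data import MotifSpec, sample_windows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def motif_spec():
    return MotifSpec(seed=0)


@pytest.fixture
def training_windows(motif_spec, rng):
    """Planted and background window samples shared across scoring tests."""
    positives = sample_windows(motif_spec, 50, planted=True, rng=rng)
    negatives = sample_windows(motif_spec, 300, planted=False, rng=rng)
    return positives, negatives


@pytest.fixture
def simple_protein():
    return ProteinRecord("P1", "AAAAAYAAAAA")


def random_window(rng) -> PeptideWindow:
    from ptpscout.sequence_library import AA20

    flanks = "".join(AA20[i] for i in rng.integers(0, 20, size=10))
    return PeptideWindow(flanks[:5] + "Y" + flanks[5:])
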