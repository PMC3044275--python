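import warnings

import numpy as np
import pytest

from helixvar.assembly import select_training_segments
from helixvar.classifier import build_training_set
from helixvar.geometry import build_ideal_helix
from helixvar.synthetic import DatasetConfig, generate_dataset


@pytest.fixture(autouse=True)
def _quiet_trace_warnings():
    # noisy synthetic traces legitimately trip the Cα–Cα distance warning
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*consecutive Cα–Cα distance.*")
        yield


@pytest.fixture(scope="session")
def ideal_octapeptide():
    """Noise-free 8-residue helix at the canonical α-helix torsions."""
    return build_ideal_helix(8)


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic corpus, generated once per session."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(DatasetConfig(), seed=1)


@pytest.fixture(scope="session")
def default_training_set(default_corpus):
    pos, neg = select_training_segments(default_corpus.segments)
    return build_training_set(pos, neg), len(pos), len(neg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
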