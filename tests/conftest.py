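import numpy as np
import pytest

from auxre_fusion import synthetic_data
from auxre_fusion.features import LABEL_POS, train_lda


@pytest.fixture(scope="session")
def fixture_promoters():
    return synthetic_data.make_fixture_promoters(length=1000, seed=0)


@pytest.fixture(scope="session")
def training_high():
    return synthetic_data.make_training_set(200, 200, separation="high", seed=1)


@pytest.fixture(scope="session")
def lda_high(training_high):
    return train_lda(training_high)


def split_half(motifs, seed=99):
    """Deterministic 50/50 train/test split."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(motifs))
    half = len(motifs) // 2
    return [motifs[i] for i in idx[:half]], [motifs[i] for i in idx[half:]]


def holdout_accuracy(motifs, seed=99, shrinkage=0.1):
    train, test = split_half(motifs, seed)
    model = train_lda(train, shrinkage=shrinkage)
    correct = [(model.score(t.context) > 0) == (t.label == LABEL_POS) for t in test]
    return float(np.mean(correct))


from hypothesis import settings as _hsettings

_hsettings.register_profile("ci", derandomize=True)
_hsettings.load_profile("ci")
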