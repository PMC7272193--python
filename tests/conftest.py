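import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lettercode import synth
from lettercode._util import all_pairs

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ALPHABET7 = "ADHIMNT"   # seven letters combined in all ways give 49 bigrams


@pytest.fixture(scope="session")
def letter_code():
    return synth.make_letter_code(10, ALPHABET7, seed=1)


@pytest.fixture(scope="session")
def bigram_weights():
    return synth.make_weights(10, 2, seed=2)


@pytest.fixture(scope="session")
def ground_truth(letter_code, bigram_weights):
    return synth.GroundTruth(letter_code=letter_code, weights=bigram_weights,
                             rt_scale=1.0, noise_sigma=0.0)


@pytest.fixture(scope="session")
def bigrams():
    return ["".join(p) for p in itertools.product(ALPHABET7, repeat=2)]


@pytest.fixture(scope="session")
def bigram_pairs(bigrams):
    return all_pairs(bigrams)


@pytest.fixture(scope="session")
def noiseless_bigram_dissim(ground_truth, bigram_pairs):
    """Observed = exact ground-truth model dissimilarities for all 1176 pairs."""
    from lettercode.strings import predict_dissimilarities
    d = predict_dissimilarities(ground_truth.letter_code, ground_truth.weights, bigram_pairs)
    return pd.DataFrame({"item_a": [p[0] for p in bigram_pairs],
                         "item_b": [p[1] for p in bigram_pairs], "d": d})


@pytest.fixture(scope="session")
def small_lexicon():
    return synth.make_lexicon(30, 5, "ABCDEFGHIJ", zipf_exponent=1.0, seed=3)


@pytest.fixture(scope="session")
def pooled_lexicon():
    """Word pool with 100/150/200 words of length 4/5/6 over 16 letters."""
    parts = [synth.make_lexicon(n, L, "ABCDEFGHIJKLMNOP", 1.0, seed=L)
             for n, L in [(100, 4), (150, 5), (200, 6)]]
    return synth.merge_lexica(parts)
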