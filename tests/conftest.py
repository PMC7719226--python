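import random

import numpy as np
import pytest
from hypothesis import settings

from mitodiv import synthetic_data

settings.register_profile("fixed", derandomize=True)
settings.load_profile("fixed")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_phylogeny(n_tips: int, seed: int, sampling_fraction: float = 1.0):
    """A random pure-birth phylogeny for oracle tests."""
    return synthetic_data._simulate_tree(
        n_tips, depth=1.0, sampling_fraction=sampling_fraction,
        min_split_frac=0.0, rng=random.Random(seed),
    )


@pytest.fixture
def toy_fasta():
    return ">ind1\nATGGCCTTT\n>ind2\nATGGCCTTC\n>ind3\nATGGCCTTT\n"
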