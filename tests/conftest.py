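import numpy as np
import pytest

from duplexmap import (FeaturizerConfig, PairRecord, RnaSequence, SynthConfig,
                       fit_length_policy, generate_pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_records():
    """A tiny deterministic labeled dataset at benchmark geometry."""
    return generate_pairs(SynthConfig(n_pairs=40, seed=7))


@pytest.fixture(scope="session")
def bench_policy(small_records):
    return fit_length_policy(small_records)


@pytest.fixture
def pair_record():
    return PairRecord(pirna=RnaSequence("GACUGGUACGUAGCAUGGAUC", id="p"),
                      site=RnaSequence("AGUCAUGCUACGUACCAGUCAAAUGCUGGAC", id="m"),
                      label=1, id="pair0")


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))
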