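import pytest

import chirdelta as cd
from chirdelta.synth import SyntheticSpec, generate_library, mock_embedder


def _curated_library(n_pairs, seed, **spec_kwargs):
    frame = generate_library(SyntheticSpec(n_pairs=n_pairs, seed=seed, **spec_kwargs))
    records, rejections = cd.curate(frame)
    assert len(rejections) == 0, "synthetic libraries must pass curation clean"
    pairs, _ = cd.build_pairs(records)
    pairs, dropped = cd.label_all_elution(records, pairs)
    assert len(dropped) == 0
    return records, pairs


@pytest.fixture(scope="session")
def mock32():
    """Deterministic 32-dimensional mock embedder (reference seed)."""
    return mock_embedder(dimension=32, seed=0)


@pytest.fixture(scope="session")
def small_library():
    """20 enantiomer pairs with labeled elution, for cheap unit tests."""
    return _curated_library(20, seed=7)


@pytest.fixture(scope="session")
def library200():
    """200 pairs for exhaustive stereo-operator and antisymmetry sweeps."""
    return _curated_library(200, seed=11)


@pytest.fixture(scope="session")
def library500():
    """500 noiseless rule-determined pairs for full-pipeline checks."""
    records, pairs = _curated_library(500, seed=0)
    split = cd.split_pairs(pairs, seed=0)
    return records, pairs, split
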