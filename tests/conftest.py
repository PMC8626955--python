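import numpy as np
import pytest
from rdkit import Chem

from smideriv import (
    SearchConfig,
    TokenVocabulary,
    TrainingConfig,
    UniformPolicy,
    build_partial_dataset,
    generate_fixture_corpus,
    split_corpus,
    train_policy,
)
from smideriv.scoring import ScoreResult


@pytest.fixture(scope="session")
def corpus():
    """60 deterministic fixture molecules."""
    return generate_fixture_corpus(60, seed=11)


@pytest.fixture(scope="session")
def corpus_200():
    return generate_fixture_corpus(200, seed=23)


@pytest.fixture(scope="session")
def dataset(corpus):
    train_mols, _ = split_corpus(corpus, 0.9, seed=11)
    return build_partial_dataset(train_mols, max_len=8)


@pytest.fixture(scope="session")
def trained_model(dataset):
    """Small LSTM trained for a few epochs; shared across tests."""
    return train_policy(
        dataset, TrainingConfig(hidden_size=64, epochs=5, batch_size=64), seed=11
    )


@pytest.fixture(scope="session")
def toy_vocab():
    return TokenVocabulary(tokens=("C", "N", "O", "<bos>", "<eos>"))


@pytest.fixture(scope="session")
def toy_policy(toy_vocab):
    return UniformPolicy(toy_vocab)


def nitrogen_fraction(smiles: str) -> ScoreResult:
    """Toy objective: fraction of heavy atoms that are nitrogen."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        raise ValueError(smiles)
    frac = sum(a.GetSymbol() == "N" for a in mol.GetAtoms()) / mol.GetNumHeavyAtoms()
    return ScoreResult(raw=frac, normalized=frac)


@pytest.fixture(scope="session")
def toy_config():
    return SearchConfig(max_fragment_len=3, max_removal_len=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
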