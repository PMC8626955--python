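"""LSTM policy: encoding, next-token softmax, sampling, rollout, training."""

import numpy as np
import pytest
from scipy.special import softmax as scipy_softmax
from scipy.stats import chisquare

from smideriv import (
    LstmPolicy,
    TokenVocabulary,
    TrainingConfig,
    UniformPolicy,
    encode,
    load_checkpoint,
    rollout_completion,
    sample_tokens,
    save_checkpoint,
    train_policy,
)
from smideriv.policy import encode_indices, perplexity, softmax
from smideriv.smiles import PartialSmilesDataset


@pytest.fixture(scope="module")
def small_vocab():
    return TokenVocabulary(tokens=("C", "N", "O", "(", ")", "<bos>", "<eos>"))


class FixedLogitsPolicy:
    """Test double: a policy with externally supplied logits."""

    def __init__(self, vocabulary, logits):
        self.vocabulary = vocabulary
        self.logits = np.asarray(logits, dtype=float)

    def next_token_distribution(self, prefix):
        return softmax(self.logits)


def test_encode_prepends_begin_sentinel(small_vocab):
    out = encode([], small_vocab)
    assert out.shape == (1, len(small_vocab))
    assert out[0, small_vocab.index_of[small_vocab.begin_token]] == 1.0

    out = encode(["C", "N"], small_vocab)
    assert out.shape == (3, len(small_vocab))
    assert np.allclose(out.sum(axis=1), 1.0)
    assert list(np.argmax(out, axis=1)) == [
        small_vocab.index_of[small_vocab.begin_token],
        small_vocab.index_of["C"],
        small_vocab.index_of["N"],
    ]


def test_encode_rejects_out_of_vocabulary(small_vocab):
    with pytest.raises(ValueError):
        encode_indices(["Zz"], small_vocab)


def test_next_token_softmax_matches_independent_softmax(small_vocab):
    """The next-token probability is exactly the softmax of the logits."""
    rng = np.random.default_rng(5)
    for _ in range(200):
        logits = rng.normal(scale=3.0, size=len(small_vocab))
        assert np.allclose(softmax(logits), scipy_softmax(logits), atol=1e-9)
    # binary case, closed form
    assert np.allclose(softmax(np.array([np.log(2.0), 0.0])), [2 / 3, 1 / 3])
    # uniform logits -> uniform distribution, exactly
    V = len(small_vocab)
    assert np.allclose(softmax(np.zeros(V)), np.full(V, 1 / V))


def test_model_distribution_normalized(trained_model):
    for prefix in ([], ["C"], ["C", "C", "("]):
        d = trained_model.next_token_distribution(prefix)
        assert d.shape == (len(trained_model.vocabulary),)
        assert np.all(d >= 0)
        assert abs(d.sum() - 1.0) < 1e-9


def test_sample_tokens_degenerate(small_vocab, rng):
    logits = np.full(len(small_vocab), -1e9)
    logits[small_vocab.index_of["N"]] = 0.0
    policy = FixedLogitsPolicy(small_vocab, logits)
    assert sample_tokens(policy, [], 7, rng) == ["N"]


def test_sample_tokens_reproducible(small_vocab):
    policy = FixedLogitsPolicy(small_vocab, np.zeros(len(small_vocab)))
    a = sample_tokens(policy, [], 5, np.random.default_rng(42))
    b = sample_tokens(policy, [], 5, np.random.default_rng(42))
    assert a == b


def test_sample_tokens_frequencies_match_distribution(small_vocab):
    """Empirical sampling frequencies pass a chi-square test at 99%."""
    rng = np.random.default_rng(7)
    logits = np.array([1.0, 0.5, 0.0, -0.5, -1.0, -1e9, 0.2])
    policy = FixedLogitsPolicy(small_vocab, logits)
    probs = softmax(logits)
    n = 100_000
    draws = rng.choice(len(probs), size=n, p=policy.next_token_distribution([]))
    counts = np.bincount(draws, minlength=len(probs))
    keep = probs > 1e-12
    _, p_value = chisquare(counts[keep], probs[keep] * n)
    assert p_value > 0.01


def test_rollout_terminates_and_flags_truncation(small_vocab, rng):
    always_eos = np.full(len(small_vocab), -1e9)
    always_eos[small_vocab.index_of[small_vocab.terminal_token]] = 0.0
    policy = FixedLogitsPolicy(small_vocab, always_eos)
    res = rollout_completion(policy, ["C"], 10, rng)
    assert res.tokens == ["C"] and not res.truncated

    never_eos = np.zeros(len(small_vocab))
    never_eos[small_vocab.index_of[small_vocab.terminal_token]] = -1e9
    policy = FixedLogitsPolicy(small_vocab, never_eos)
    res = rollout_completion(policy, [], 6, rng)
    assert len(res.tokens) == 6 and res.truncated


def test_rollout_reproducible_and_prefix_preserved(trained_model):
    a = rollout_completion(trained_model, ["C", "C"], 12, np.random.default_rng(3))
    b = rollout_completion(trained_model, ["C", "C"], 12, np.random.default_rng(3))
    assert a.tokens == b.tokens
    assert a.tokens[:2] == ["C", "C"]
    assert len(a.tokens) <= 12


def test_training_decreases_loss(trained_model):
    trace = trained_model.loss_trace
    assert len(trace) == 5
    assert trace[-1] < trace[0]


def test_training_deterministic():
    ds = PartialSmilesDataset(
        fragments=("C", "CC", "CO", "N"), source_count=2, filter_stats={}
    )
    cfg = TrainingConfig(hidden_size=12, epochs=4, batch_size=2)
    m1 = train_policy(ds, cfg, seed=9)
    m2 = train_policy(ds, cfg, seed=9)
    assert m1.loss_trace == m2.loss_trace
    assert all(np.array_equal(m1.params[k], m2.params[k]) for k in m1.params)


def test_single_fragment_overfit():
    ds = PartialSmilesDataset(fragments=("C",), source_count=1, filter_stats={})
    model = train_policy(
        ds,
        TrainingConfig(hidden_size=16, epochs=300, batch_size=4, learning_rate=5e-3),
        seed=0,
    )
    d = model.next_token_distribution([])
    assert d[model.vocabulary.index_of["C"]] > 0.9


def test_trained_model_beats_untrained_perplexity(dataset, trained_model):
    """Held-out fragments are less surprising to the trained model."""
    held_out = dataset.fragments[::7][:40]
    untrained = LstmPolicy(
        trained_model.vocabulary, hidden_size=64, rng=np.random.default_rng(1)
    )
    assert perplexity(trained_model, held_out) < perplexity(untrained, held_out)


def test_checkpoint_round_trip(trained_model, tmp_path):
    path = tmp_path / "model.npz"
    save_checkpoint(trained_model, path)
    loaded = load_checkpoint(path)
    assert loaded.vocabulary.tokens == trained_model.vocabulary.tokens
    assert all(
        np.array_equal(loaded.params[k], trained_model.params[k])
        for k in trained_model.params
    )
    d1 = trained_model.next_token_distribution(["C"])
    d2 = loaded.next_token_distribution(["C"])
    assert np.allclose(d1, d2)


def test_uniform_policy_excludes_begin(small_vocab):
    d = UniformPolicy(small_vocab).next_token_distribution([])
    assert d[small_vocab.index_of[small_vocab.begin_token]] == 0.0
    assert abs(d.sum() - 1.0) < 1e-12
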