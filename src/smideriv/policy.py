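"""Next-token policy over partial-SMILES fragments.

A two-layer LSTM language model assigns a probability to each vocabulary token
given a fragment prefix.  The search tree uses it twice: during *expansion* a
fixed number of samples from the next-token distribution proposes child tokens,
and during *simulation* the model is the rollout policy that completes a
fragment until it emits the terminal sentinel.

The network is implemented directly in NumPy (batched forward pass, full
backpropagation through time, Adam) so that training is single-threaded and
bit-reproducible for a fixed seed.  Models at fragment scale are small; CPU
training takes seconds to minutes.

Training sequences are ``begin + fragment + terminal``; the model is trained
with teacher forcing to minimise the mean per-position cross-entropy.  The
next-token probability is the softmax of the final-position logits,

    P(s_i | s_1 ... s_t) = exp(y_i) / sum_j exp(y_j).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .smiles import TokenVocabulary

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1

# Gate slices within the stacked 4H pre-activation: input, forget, cell, output.
_GATES = ("i", "f", "g", "o")


@dataclass
class TrainingConfig:
    """Hyperparameters of the LSTM policy.

    Defaults are standard SMILES language-model settings; none of the search
    behaviour depends on them beyond the quality of the proposals.
    """

    hidden_size: int = 256
    epochs: int = 20
    batch_size: int = 128
    learning_rate: float = 1e-3
    clip_norm: float = 5.0
    init_scale: float = 0.08


class Policy(Protocol):
    """Anything the tree can sample from: a vocabulary plus P(next token | prefix)."""

    vocabulary: TokenVocabulary

    def next_token_distribution(self, prefix: Sequence[str]) -> np.ndarray: ...


def encode(seq: Sequence[str], vocab: TokenVocabulary) -> np.ndarray:
    """One-hot encode ``begin + seq`` as a (len(seq)+1, V) indicator matrix."""
    idx = encode_indices(seq, vocab)
    out = np.zeros((len(idx), len(vocab)))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def encode_indices(seq: Sequence[str], vocab: TokenVocabulary) -> np.ndarray:
    """Integer encoding of ``begin + seq``; raises on out-of-vocabulary tokens."""
    try:
        body = [vocab.index_of[t] for t in seq]
    except KeyError as exc:
        raise ValueError(f"token {exc.args[0]!r} not in vocabulary") from None
    return np.array([vocab.index_of[vocab.begin_token]] + body, dtype=np.int64)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def _init_params(V: int, H: int, rng: np.random.Generator, scale: float) -> dict:
    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)

    params = {
        "Wx0": u(V, 4 * H), "Wh0": u(H, 4 * H), "b0": np.zeros(4 * H),
        "Wx1": u(H, 4 * H), "Wh1": u(H, 4 * H), "b1": np.zeros(4 * H),
        "Wy": u(H, V), "by": np.zeros(V),
    }
    # Positive forget-gate bias: standard LSTM trick for gradient flow early on.
    for b in ("b0", "b1"):
        params[b][H : 2 * H] = 1.0
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_cell(a: np.ndarray, c_prev: np.ndarray, H: int):
    i = _sigmoid(a[:, :H])
    f = _sigmoid(a[:, H : 2 * H])
    g = np.tanh(a[:, 2 * H : 3 * H])
    o = _sigmoid(a[:, 3 * H :])
    c = f * c_prev + i * g
    tanh_c = np.tanh(c)
    h = o * tanh_c
    return i, f, g, o, c, tanh_c, h


class LstmPolicy:
    """Two-layer LSTM next-token model over the fragment vocabulary."""

    def __init__(
        self,
        vocabulary: TokenVocabulary,
        hidden_size: int,
        params: dict | None = None,
        rng: np.random.Generator | None = None,
        init_scale: float = 0.08,
        metadata: dict | None = None,
    ):
        self.vocabulary = vocabulary
        self.hidden_size = hidden_size
        if params is None:
            rng = rng if rng is not None else np.random.default_rng(0)
            params = _init_params(len(vocabulary), hidden_size, rng, init_scale)
        self.params = params
        self.metadata = metadata or {}
        self.loss_trace: list[float] = list(self.metadata.get("loss_trace", []))

    # ---------------------------------------------------------------- forward

    def _forward(self, x_idx: np.ndarray):
        """Batched forward pass.

        x_idx: (B, T) input token indices.  Returns logits (B, T, V) and the
        per-step caches needed for backpropagation.
        """
        p, H = self.params, self.hidden_size
        B, T = x_idx.shape
        h = [np.zeros((B, H)), np.zeros((B, H))]
        c = [np.zeros((B, H)), np.zeros((B, H))]
        logits = np.empty((B, T, len(self.vocabulary)))
        cache0, cache1 = [], []
        for t in range(T):
            xt = x_idx[:, t]
            a0 = p["Wx0"][xt] + h[0] @ p["Wh0"] + p["b0"]
            i0, f0, g0, o0, c0, th0, h0 = _lstm_cell(a0, c[0], H)
            cache0.append((xt, h[0], c[0], i0, f0, g0, o0, c0, th0))
            h[0], c[0] = h0, c0

            a1 = h0 @ p["Wx1"] + h[1] @ p["Wh1"] + p["b1"]
            i1, f1, g1, o1, c1, th1, h1 = _lstm_cell(a1, c[1], H)
            cache1.append((h0, h[1], c[1], i1, f1, g1, o1, c1, th1))
            h[1], c[1] = h1, c1

            logits[:, t] = h1 @ p["Wy"] + p["by"]
        return logits, (cache0, cache1)

    @staticmethod
    def _cell_backward(cache_t, dh, dc_next, H):
        x, h_prev, c_prev, i, f, g, o, c, tanh_c = cache_t
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c**2)
        da = np.concatenate(
            [
                dc * g * i * (1.0 - i),
                dc * c_prev * f * (1.0 - f),
                dc * i * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        return da, dc * f, x, h_prev

    def _backward(self, dlogits: np.ndarray, caches) -> dict:
        """Gradients of the masked cross-entropy w.r.t. every parameter."""
        p, H = self.params, self.hidden_size
        cache0, cache1 = caches
        T = len(cache0)
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        # Output layer and second LSTM layer (reverse time), collecting the
        # gradient w.r.t. the first layer's hidden states as we go.
        dh1_from_x = [None] * T
        dh_next, dc_next = 0.0, 0.0
        for t in reversed(range(T)):
            x1, h_prev, c_prev, i, f, g, o, c, tanh_c = cache1[t]
            h1 = o * tanh_c
            dl = dlogits[:, t]
            grads["Wy"] += h1.T @ dl
            grads["by"] += dl.sum(axis=0)
            dh = dl @ p["Wy"].T + dh_next
            da, dc_next, x_in, hp = self._cell_backward(cache1[t], dh, dc_next, H)
            grads["Wx1"] += x_in.T @ da
            grads["Wh1"] += hp.T @ da
            grads["b1"] += da.sum(axis=0)
            dh_next = da @ p["Wh1"].T
            dh1_from_x[t] = da @ p["Wx1"].T

        dh_next, dc_next = 0.0, 0.0
        for t in reversed(range(T)):
            dh = dh1_from_x[t] + dh_next
            da, dc_next, x_idx_t, hp = self._cell_backward(cache0[t], dh, dc_next, H)
            np.add.at(grads["Wx0"], x_idx_t, da)
            grads["Wh0"] += hp.T @ da
            grads["b0"] += da.sum(axis=0)
            dh_next = da @ p["Wh0"].T
        return grads

    # -------------------------------------------------------------- inference

    def next_token_distribution(self, prefix: Sequence[str]) -> np.ndarray:
        """P(next token | prefix): softmax of the final-position logits."""
        x = encode_indices(prefix, self.vocabulary)[None, :]
        logits, _ = self._forward(x)
        return softmax(logits[0, -1])


class UniformPolicy:
    """Uniform next-token distribution; the no-learning baseline policy."""

    def __init__(self, vocabulary: TokenVocabulary):
        self.vocabulary = vocabulary

    def next_token_distribution(self, prefix: Sequence[str]) -> np.ndarray:
        V = len(self.vocabulary)
        p = np.full(V, 1.0 / (V - 1))
        p[self.vocabulary.index_of[self.vocabulary.begin_token]] = 0.0
        return p


def sample_tokens(
    model: Policy, prefix: Sequence[str], k: int, rng: np.random.Generator
) -> list[str]:
    """Draw k tokens from the next-token distribution; distinct, first-draw order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    probs = model.next_token_distribution(prefix)
    draws = rng.choice(len(probs), size=k, p=probs)
    seen: list[str] = []
    for d in draws:
        tok = model.vocabulary.tokens[int(d)]
        if tok not in seen:
            seen.append(tok)
    return seen


@dataclass
class RolloutResult:
    """Fragment completed by the default policy; ``truncated`` marks a
    completion cut off at ``max_len`` before the terminal sentinel appeared."""

    tokens: list[str]
    truncated: bool


def rollout_completion(
    model: Policy, prefix: Sequence[str], max_len: int, rng: np.random.Generator
) -> RolloutResult:
    """Sample one token at a time until the terminal sentinel or ``max_len``."""
    if len(prefix) > max_len:
        raise ValueError("prefix longer than max_len")
    vocab = model.vocabulary
    tokens = list(prefix)
    terminal = vocab.terminal_token
    while len(tokens) < max_len:
        probs = model.next_token_distribution(tokens)
        tok = vocab.tokens[int(rng.choice(len(probs), p=probs))]
        if tok == terminal:
            return RolloutResult(tokens=tokens, truncated=False)
        tokens.append(tok)
    return RolloutResult(tokens=tokens, truncated=True)


# ------------------------------------------------------------------- training


def _batch_arrays(fragments_idx: list[list[int]], vocab: TokenVocabulary):
    """Pad a batch: inputs are begin+fragment, targets fragment+terminal."""
    begin = vocab.index_of[vocab.begin_token]
    terminal = vocab.index_of[vocab.terminal_token]
    B = len(fragments_idx)
    T = max(len(f) for f in fragments_idx) + 1
    x = np.zeros((B, T), dtype=np.int64)
    y = np.zeros((B, T), dtype=np.int64)
    mask = np.zeros((B, T))
    for b, frag in enumerate(fragments_idx):
        L = len(frag) + 1
        x[b, 0] = begin
        x[b, 1:L] = frag
        y[b, : L - 1] = frag
        y[b, L - 1] = terminal
        mask[b, :L] = 1.0
    return x, y, mask


def _adam_step(params, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    for k in params:
        m, v = state[k]
        m[:] = beta1 * m + (1 - beta1) * grads[k]
        v[:] = beta2 * v + (1 - beta2) * grads[k] ** 2
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def corpus_fingerprint(fragments: Sequence[str]) -> str:
    h = hashlib.sha256("\n".join(fragments).encode()).hexdigest()
    return h[:16]


def train_policy(
    dataset,
    config: TrainingConfig | None = None,
    seed: int = 0,
) -> LstmPolicy:
    """Train the two-layer LSTM on a :class:`PartialSmilesDataset`.

    Teacher-forced cross-entropy over ``begin + fragment + terminal``
    sequences, Adam optimiser, global-norm gradient clipping.  Deterministic
    for a fixed seed.  The per-epoch mean per-token loss is stored on
    ``model.loss_trace``.
    """
    from .smiles import tokenize  # local import to avoid cycles at module load

    config = config or TrainingConfig()
    fragments = list(dataset.fragments)
    if not fragments:
        raise ValueError("dataset is empty")
    vocab = TokenVocabulary.from_fragments(fragments)
    frag_idx = [[vocab.index_of[t] for t in tokenize(f)] for f in fragments]

    rng = np.random.default_rng(seed)
    model = LstmPolicy(
        vocab, config.hidden_size, rng=rng, init_scale=config.init_scale
    )
    p = model.params
    adam_state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in p.items()}
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(frag_idx))
        total_loss = 0.0
        total_tokens = 0.0
        for lo in range(0, len(order), config.batch_size):
            batch = [frag_idx[i] for i in order[lo : lo + config.batch_size]]
            x, y, mask = _batch_arrays(batch, vocab)
            logits, caches = model._forward(x)
            probs = softmax(logits)
            B, T, V = probs.shape
            picked = probs[np.arange(B)[:, None], np.arange(T)[None, :], y]
            n_tok = mask.sum()
            loss = -(np.log(np.clip(picked, 1e-12, None)) * mask).sum()
            total_loss += loss
            total_tokens += n_tok

            dlogits = probs.copy()
            dlogits[np.arange(B)[:, None], np.arange(T)[None, :], y] -= 1.0
            dlogits *= (mask / n_tok)[:, :, None]
            grads = model._backward(dlogits, caches)
            gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if gnorm > config.clip_norm:
                scale = config.clip_norm / gnorm
                for g in grads.values():
                    g *= scale
            step += 1
            _adam_step(p, grads, adam_state, config.learning_rate, step)
        model.loss_trace.append(total_loss / total_tokens)
        logger.info(
            "epoch %d/%d: mean cross-entropy %.4f",
            epoch + 1, config.epochs, model.loss_trace[-1],
        )

    model.metadata = {
        "epochs": config.epochs,
        "seed": seed,
        "corpus_fingerprint": corpus_fingerprint(fragments),
        "loss_trace": list(model.loss_trace),
    }
    return model


def perplexity(model: LstmPolicy, fragments: Sequence[str]) -> float:
    """exp(mean per-token cross-entropy) of the model on held-out fragments."""
    from .smiles import tokenize

    vocab = model.vocabulary
    total, n = 0.0, 0
    for frag in fragments:
        toks = tokenize(frag)
        idx = [vocab.index_of[t] for t in toks]
        x, y, mask = _batch_arrays([idx], vocab)
        logits, _ = model._forward(x)
        probs = softmax(logits)[0]
        picked = probs[np.arange(len(y[0])), y[0]]
        total += -(np.log(np.clip(picked, 1e-12, None)) * mask[0]).sum()
        n += int(mask.sum())
    return float(np.exp(total / n))


# ----------------------------------------------------------------- checkpoint


def _vocab_hash(vocab: TokenVocabulary) -> str:
    return hashlib.sha256("\x00".join(vocab.tokens).encode()).hexdigest()[:16]


def save_checkpoint(model: LstmPolicy, path) -> None:
    """Write a versioned .npz archive: weights + vocabulary + config metadata."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "hidden_size": model.hidden_size,
        "tokens": list(model.vocabulary.tokens),
        "begin_token": model.vocabulary.begin_token,
        "terminal_token": model.vocabulary.terminal_token,
        "vocab_hash": _vocab_hash(model.vocabulary),
        "metadata": model.metadata,
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.params)


def load_checkpoint(path) -> LstmPolicy:
    """Load a checkpoint, validating the schema version and vocabulary hash."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        vocab = TokenVocabulary(
            tokens=tuple(meta["tokens"]),
            begin_token=meta["begin_token"],
            terminal_token=meta["terminal_token"],
        )
        if _vocab_hash(vocab) != meta["vocab_hash"]:
            raise ValueError("vocabulary hash mismatch: corrupt checkpoint")
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    return LstmPolicy(
        vocab, meta["hidden_size"], params=params, metadata=meta["metadata"]
    )
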