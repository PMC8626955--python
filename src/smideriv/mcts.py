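"""Monte Carlo tree search over seed-SMILES edits.

The tree has a fixed first layer of *replacement nodes*, one per
``(start, length)`` span of the seed that may be deleted; fragment generation
begins at their children.  A root-to-leaf path below a replacement node spells
a partial SMILES, one vocabulary token per node.  Each search step runs the
classic four-phase cycle:

1. **Selection** — descend from the root by the UCB tree policy
   ``Q(s_i) + 2 C_p sqrt(ln N(s_p) / N(s_i))`` until a leaf.
2. **Expansion** — if the leaf has been visited before, propose child tokens
   by sampling the next-token policy a fixed number of times.
3. **Simulation** — complete the leaf's fragment with policy rollouts, splice
   it into the seed at the replacement span, and score the resulting molecule
   (invalid strings earn the invalid reward).
4. **Backpropagation** — update every node on the path with the incremental
   mean ``Q <- (Q N + r) / (N + 1)``, ``N <- N + 1``.

Rewards are normalized to [0, 1], the range under which UCB's regret guarantee
holds.  C_p defaults to 1/sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .policy import Policy, rollout_completion, sample_tokens
from .scoring import ScoreResult, tanimoto_similarity
from .smiles import ReplacementSpec, detokenize, is_valid_smiles, splice, tokenize

DEFAULT_CP = 1.0 / math.sqrt(2.0)


@dataclass
class SearchConfig:
    """Search hyperparameters.

    ``c_p`` weighs exploration against exploitation; ``expansion_samples`` is
    the number of draws from the policy when proposing children;
    ``max_fragment_len`` caps generated fragments (tokens);
    ``max_removal_len`` caps the deleted span (tokens), keeping the first
    layer linear rather than quadratic in seed length; ``invalid_reward`` is
    the [0,1] reward assigned to unparseable or rejected candidates.
    """

    c_p: float = DEFAULT_CP
    expansion_samples: int = 10
    max_fragment_len: int = 20
    max_removal_len: int = 10
    invalid_reward: float = 0.0

    def __post_init__(self) -> None:
        if self.c_p <= 0:
            raise ValueError("c_p must be positive")
        if not 0.0 <= self.invalid_reward <= 1.0:
            raise ValueError("invalid_reward must lie in [0, 1]")


class SearchNode:
    """One tree node: a token (or replacement/root marker), Q, N, children."""

    __slots__ = ("token", "spec", "fragment", "Q", "N", "children", "parent")

    def __init__(
        self,
        token: Optional[str] = None,
        spec: Optional[ReplacementSpec] = None,
        fragment: tuple[str, ...] = (),
        parent: Optional["SearchNode"] = None,
    ):
        self.token = token
        self.spec = spec
        self.fragment = fragment
        self.Q = 0.0
        self.N = 0
        self.children: list[SearchNode] = []
        self.parent = parent

    @property
    def is_root(self) -> bool:
        return self.parent is None

    @property
    def is_replacement(self) -> bool:
        return self.parent is not None and self.parent.parent is None

    def __repr__(self) -> str:  # debugging aid
        tag = "root" if self.is_root else (self.spec if self.is_replacement else self.token)
        return f"SearchNode({tag}, Q={self.Q:.3f}, N={self.N})"


@dataclass
class GenerationRecord:
    """One simulated molecule: the candidate string, its score and provenance."""

    smiles: str
    valid: bool
    raw_score: float
    normalized_reward: float
    step: int
    cycle: int
    replacement: ReplacementSpec
    fragment: str
    similarity_to_seed: float = math.nan


def build_replacement_layer(seed: str, max_removal_len: int) -> SearchNode:
    """Root plus one child per (start, length) deletion span of the seed.

    All spans with ``0 <= start <= T`` and ``0 <= length <= min(max_removal_len,
    T - start)`` are enumerated (start = T, length = 0 is a pure append).
    """
    if max_removal_len < 0:
        raise ValueError("max_removal_len must be >= 0")
    if not is_valid_smiles(seed):
        raise ValueError(f"seed is not a valid molecule: {seed!r}")
    T = len(tokenize(seed))
    root = SearchNode()
    for start in range(T + 1):
        for length in range(min(max_removal_len, T - start) + 1):
            spec = ReplacementSpec(start=start, length=length)
            root.children.append(SearchNode(spec=spec, parent=root))
    return root


def ucb_score(child: SearchNode, parent_visits: int, c_p: float) -> float:
    if child.N == 0:
        return math.inf
    return child.Q + 2.0 * c_p * math.sqrt(math.log(parent_visits) / child.N)


def ucb_select(parent: SearchNode, c_p: float) -> SearchNode:
    """Argmax child under the UCB score; unvisited first; ties to lowest index."""
    if not parent.children:
        raise ValueError("cannot select from a childless node")
    best, best_score = None, -math.inf
    for child in parent.children:
        s = ucb_score(child, max(parent.N, 1), c_p)
        if s > best_score:
            best, best_score = child, s
    return best


def select_path(root: SearchNode, c_p: float) -> list[SearchNode]:
    """Descend by UCB from the root to a leaf; returns the visited path."""
    path = [root]
    node = root
    while node.children:
        node = ucb_select(node, c_p)
        path.append(node)
    return path


def expand(
    leaf: SearchNode,
    model: Policy,
    k: int,
    rng: np.random.Generator,
    max_fragment_len: int = 20,
) -> list[SearchNode]:
    """Attach children sampled from the policy's next-token distribution.

    A leaf whose fragment already reached ``max_fragment_len`` receives only
    the terminal child.  Terminal-token leaves are complete fragments and are
    never expanded.
    """
    terminal = model.vocabulary.terminal_token
    if leaf.token == terminal:
        return []
    if len(leaf.fragment) >= max_fragment_len:
        tokens = [terminal]
    else:
        tokens = sample_tokens(model, list(leaf.fragment), k, rng)
    for tok in tokens:
        frag = leaf.fragment if tok == terminal else leaf.fragment + (tok,)
        leaf.children.append(
            SearchNode(token=tok, spec=leaf.spec, fragment=frag, parent=leaf)
        )
    return leaf.children


def simulate(
    leaf: SearchNode,
    model: Policy,
    seed: str,
    spec: ReplacementSpec,
    reward_fn: Callable[[str], ScoreResult],
    config: SearchConfig,
    rng: np.random.Generator,
    cache: Optional[dict] = None,
    similarity_reference: Optional[str] = None,
    step: int = 0,
    cycle: int = 0,
) -> tuple[float, GenerationRecord]:
    """Rollout, splice, score.  All chemistry failures map to invalid_reward."""
    terminal = model.vocabulary.terminal_token
    if leaf.token == terminal:
        fragment = list(leaf.fragment)
    else:
        fragment = rollout_completion(
            model, list(leaf.fragment), config.max_fragment_len, rng
        ).tokens
    frag_text = detokenize(fragment)
    candidate = splice(seed, spec, frag_text)

    key = candidate
    if cache is not None and key in cache:
        valid, raw, normalized, sim = cache[key]
    else:
        valid = is_valid_smiles(candidate)
        raw, normalized, sim = math.nan, config.invalid_reward, math.nan
        if valid:
            try:
                result = reward_fn(candidate)
                raw, normalized = result.raw, result.normalized
            except Exception:
                valid = False
            else:
                reference = similarity_reference or seed
                try:
                    sim = tanimoto_similarity(candidate, reference)
                except ValueError:
                    sim = math.nan
        if cache is not None:
            cache[key] = (valid, raw, normalized, sim)

    record = GenerationRecord(
        smiles=candidate,
        valid=valid,
        raw_score=raw,
        normalized_reward=normalized,
        step=step,
        cycle=cycle,
        replacement=spec,
        fragment=frag_text,
        similarity_to_seed=sim,
    )
    return normalized, record


def backpropagate(path: Sequence[SearchNode], r: float) -> None:
    """Incremental-mean update along the whole path."""
    for node in path:
        node.Q = (node.Q * node.N + r) / (node.N + 1)
        node.N += 1


def run_search(
    seed: str,
    model: Policy,
    reward_fn: Callable[[str], ScoreResult],
    steps: int,
    config: SearchConfig | None = None,
    rng: np.random.Generator | int | None = None,
    cache: Optional[dict] = None,
    similarity_reference: Optional[str] = None,
    cycle: int = 0,
    step_offset: int = 0,
) -> list[GenerationRecord]:
    """Run ``steps`` search iterations from a fresh tree; return every simulation.

    Every simulated molecule — valid or not — yields one
    :class:`GenerationRecord`.  Duplicate candidates are re-recorded but their
    score is reused from the cache.  Deterministic for a fixed rng seed.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    config = config or SearchConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if cache is None:
        cache = {}
    root = build_replacement_layer(seed, config.max_removal_len)
    terminal = model.vocabulary.terminal_token
    records: list[GenerationRecord] = []
    for step in range(steps):
        path = select_path(root, config.c_p)
        leaf = path[-1]
        if leaf.N > 0 and not leaf.is_root and leaf.token != terminal:
            if expand(leaf, model, config.expansion_samples, rng,
                      config.max_fragment_len):
                leaf = ucb_select(leaf, config.c_p)
                path.append(leaf)
        r, record = simulate(
            leaf, model, seed, leaf.spec, reward_fn, config, rng,
            cache=cache, similarity_reference=similarity_reference,
            step=step_offset + step, cycle=cycle,
        )
        backpropagate(path, r)
        records.append(record)
    return records
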