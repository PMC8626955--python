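"""Tree search: replacement layer, UCB selection, expansion, backpropagation."""

import math

import numpy as np
import pytest

from smideriv import (
    ReplacementSpec,
    SearchConfig,
    SearchNode,
    backpropagate,
    build_replacement_layer,
    expand,
    run_search,
    select_path,
    simulate,
    tokenize,
    ucb_select,
)
from smideriv.policy import UniformPolicy

from conftest import nitrogen_fraction


def _ucb_reference(Q, N_child, N_parent, c_p):
    if N_child == 0:
        return math.inf
    return Q + 2 * c_p * math.sqrt(math.log(N_parent) / N_child)


def _make_parent(children_stats, parent_N):
    parent = SearchNode()
    parent.N = parent_N
    for Q, N in children_stats:
        child = SearchNode(token="C", parent=parent)
        child.Q, child.N = Q, N
        parent.children.append(child)
    return parent


def test_replacement_layer_single_token_seed():
    root = build_replacement_layer("C", max_removal_len=1)
    specs = {(c.spec.start, c.spec.length) for c in root.children}
    assert specs == {(0, 0), (0, 1), (1, 0)}


def test_replacement_layer_unbounded_count(corpus):
    """With no removal cap the layer has (T+1)(T+2)/2 nodes: one per
    (start, length) pair."""
    for seed in corpus[:10]:
        T = len(tokenize(seed))
        root = build_replacement_layer(seed, max_removal_len=T)
        assert len(root.children) == (T + 1) * (T + 2) // 2
        for child in root.children:
            assert child.spec.start + child.spec.length <= T


def test_replacement_layer_respects_cap():
    root = build_replacement_layer("CCCCCC", max_removal_len=2)
    assert max(c.spec.length for c in root.children) == 2


def test_replacement_layer_rejects_invalid_seed():
    with pytest.raises(ValueError):
        build_replacement_layer("C(", 2)


def test_ucb_select_matches_brute_force():
    """argmax of the UCB formula on 1000 random small trees."""
    rng = np.random.default_rng(12)
    c_p = 1 / math.sqrt(2)
    for _ in range(1000):
        n_children = int(rng.integers(1, 8))
        stats = [
            (float(rng.uniform(0, 1)), int(rng.integers(1, 30)))
            for _ in range(n_children)
        ]
        parent_N = max(int(rng.integers(1, 100)), sum(n for _, n in stats))
        parent = _make_parent(stats, parent_N)
        scores = [_ucb_reference(q, n, parent_N, c_p) for q, n in stats]
        expected = int(np.argmax(scores))
        assert ucb_select(parent, c_p) is parent.children[expected]


def test_ucb_example_from_formula():
    # parent N=10, children (Q=.5,N=5) and (Q=.2,N=1): exploration wins
    parent = _make_parent([(0.5, 5), (0.2, 1)], 10)
    assert ucb_select(parent, 1 / math.sqrt(2)) is parent.children[1]


def test_ucb_unvisited_first_and_tie_break():
    parent = _make_parent([(0.9, 4), (0.0, 0)], 5)
    assert ucb_select(parent, 0.5) is parent.children[1]
    # exact ties resolve to the lowest-index child
    parent = _make_parent([(0.5, 3), (0.5, 3), (0.5, 3)], 9)
    assert ucb_select(parent, 0.5) is parent.children[0]
    with pytest.raises(ValueError):
        ucb_select(SearchNode(), 0.5)


def test_ucb_cp_to_zero_is_greedy():
    parent = _make_parent([(0.3, 1), (0.8, 50), (0.5, 2)], 60)
    assert ucb_select(parent, 1e-12) is parent.children[1]


def test_select_path_structure():
    root = SearchNode()
    assert select_path(root, 0.5) == [root]
    parent = _make_parent([(0.2, 2), (0.7, 2)], 4)
    path = select_path(parent, 1e-12)
    assert path == [parent, parent.children[1]]
    for a, b in zip(path, path[1:]):
        assert b.parent is a


def test_expand_contracts(toy_vocab, rng):
    policy = UniformPolicy(toy_vocab)
    leaf = SearchNode(token="C", spec=ReplacementSpec(0, 0), fragment=("C",))
    leaf.parent = SearchNode()  # not root-layer semantics, just non-root
    children = expand(leaf, policy, k=50, rng=rng, max_fragment_len=5)
    tokens = [c.token for c in children]
    assert len(tokens) == len(set(tokens))  # distinct
    assert set(tokens) <= set(toy_vocab.tokens)
    # a leaf at the fragment cap only gets the terminal child
    capped = SearchNode(token="C", fragment=("C",) * 5)
    assert [c.token for c in expand(capped, policy, 10, rng, max_fragment_len=5)] == [
        toy_vocab.terminal_token
    ]
    # terminal leaves never expand
    term = SearchNode(token=toy_vocab.terminal_token)
    assert expand(term, policy, 10, rng, 5) == []
    # k=1 yields at most one child
    single = SearchNode(token="C", fragment=("C",))
    assert len(expand(single, policy, 1, rng, 5)) <= 1


def test_backpropagate_incremental_mean():
    rng = np.random.default_rng(3)
    for _ in range(1000):
        Q = float(rng.uniform(0, 1))
        N = int(rng.integers(0, 50))
        r = float(rng.uniform(0, 1))
        node = SearchNode()
        node.Q, node.N = Q, N
        backpropagate([node], r)
        assert node.N == N + 1
        assert node.Q == pytest.approx((Q * N + r) / (N + 1), abs=1e-12)

    node = SearchNode()
    rewards = rng.uniform(0, 1, size=25)
    for r in rewards:
        backpropagate([node], float(r))
    assert node.Q == pytest.approx(float(np.mean(rewards)), abs=1e-12)
    assert node.N == len(rewards)


def test_backpropagate_first_visit():
    node = SearchNode()
    backpropagate([node], 0.8)
    assert (node.Q, node.N) == (0.8, 1)


def test_simulate_invalid_fragment_gets_invalid_reward(toy_vocab, rng):
    policy = UniformPolicy(toy_vocab)
    cfg = SearchConfig(max_fragment_len=3, max_removal_len=2, invalid_reward=0.0)
    # terminal leaf with a fragment that breaks the molecule: "CCO" with the
    # whole string removed and nothing inserted -> "" which does not parse
    leaf = SearchNode(
        token=toy_vocab.terminal_token, spec=ReplacementSpec(0, 3), fragment=()
    )
    r, rec = simulate(
        leaf, policy, "CCO", leaf.spec, nitrogen_fraction, cfg, rng
    )
    assert r == 0.0 and not rec.valid and math.isnan(rec.raw_score)


def test_simulate_terminal_shortcut_scores_fragment(toy_vocab, rng):
    policy = UniformPolicy(toy_vocab)
    cfg = SearchConfig(max_fragment_len=3, max_removal_len=2)
    leaf = SearchNode(
        token=toy_vocab.terminal_token, spec=ReplacementSpec(1, 1), fragment=("N",)
    )
    r, rec = simulate(leaf, policy, "CCO", leaf.spec, nitrogen_fraction, cfg, rng)
    assert rec.smiles == "CNO" and rec.valid
    assert r == pytest.approx(nitrogen_fraction("CNO").normalized)
    assert rec.fragment == "N"


def test_run_search_bookkeeping(toy_policy, toy_config):
    records = run_search("CCO", toy_policy, nitrogen_fraction, 1, toy_config, rng=0)
    assert len(records) == 1

    records = run_search("CCO", toy_policy, nitrogen_fraction, 300, toy_config, rng=0)
    assert len(records) == 300
    for rec in records:
        if rec.valid:
            assert 0.0 <= rec.normalized_reward <= 1.0
        else:
            assert rec.normalized_reward == toy_config.invalid_reward


def test_run_search_conservation_and_q_range(toy_policy, toy_config):
    """root.N equals completed simulations; convex updates keep Q in [0,1]."""
    import smideriv.mcts as m

    root_holder = {}
    original = m.build_replacement_layer

    def capture(seed, cap):
        root = original(seed, cap)
        root_holder["root"] = root
        return root

    m.build_replacement_layer = capture
    try:
        run_search("CCO", toy_policy, nitrogen_fraction, 500, toy_config, rng=1)
    finally:
        m.build_replacement_layer = original
    root = root_holder["root"]
    assert root.N == 500

    def walk(node):
        assert 0.0 <= node.Q <= 1.0
        assert all(node.N >= c.N for c in node.children)
        for c in node.children:
            walk(c)

    walk(root)


def test_run_search_deterministic(toy_policy, toy_config):
    a = run_search("CCO", toy_policy, nitrogen_fraction, 200, toy_config, rng=7)
    b = run_search("CCO", toy_policy, nitrogen_fraction, 200, toy_config, rng=7)
    assert [r.smiles for r in a] == [r.smiles for r in b]
    assert [r.normalized_reward for r in a] == [r.normalized_reward for r in b]
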