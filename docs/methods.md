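# Methods

## The generation model

`smideriv` treats derivative generation as planning in the space of
single-span string edits of a seed SMILES. An edit is a pair: a
`ReplacementSpec (start, length)` naming a contiguous token span of the seed
to delete, and a partial SMILES to insert in its place. Editing is purely
lexical — no valence checking, no ring-closure repair — so many candidates do
not parse; unparseable candidates simply receive the invalid reward and the
search learns to avoid the branches that produce them.

Tokens, not characters, are the unit of editing: `Cl`, `Br`, bracket atoms
(`[nH]`, `[O-]`) and two-digit ring closures (`%12`) are single tokens, so an
edit can never split a lexical unit. The tokenizer covers the organic subset,
aromatic lowercase atoms, bonds, branches, ring-closure digits and bracket
atoms, and rejects anything else.

### Search tree

The root's children are the replacement nodes, pre-enumerated for every
`(start, length)` with `length ≤ max_removal_len` (default 10 tokens; the
full enumeration is quadratic in seed length, and the cap keeps the layer
linear). Grandchildren onward each carry one vocabulary token; a path spells
the inserted fragment, completed when the terminal sentinel is chosen.

Each iteration: **selection** descends by
`argmax_i { Q(s_i) + 2 C_p √(ln N(s_p)/N(s_i)) }` with `C_p = 1/√2`, the
standard choice when rewards lie in [0, 1]. Unvisited children score +∞
(visit-each-once-first, the usual UCT convention — the formula is undefined
at `N = 0`), and exact ties resolve to the lowest-index child so runs are
reproducible. **Expansion** of a previously visited leaf draws
`expansion_samples` (default 10) tokens from the policy's next-token
distribution and attaches the distinct ones; a leaf at the fragment cap gets
only the terminal child; one rollout is then run from one of the new
children. **Simulation** completes the fragment by sampling the policy until
the terminal token (or `max_fragment_len`, default 20 tokens, with the
truncation flagged), splices it into the seed, and scores the product.
**Backpropagation** applies `Q ← (Q·N + r)/(N+1)`, `N ← N+1` along the whole
path; since this is a convex combination, rewards in [0, 1] keep every `Q`
in [0, 1], and the root's `N` counts completed simulations exactly.

Every simulation is recorded, valid or not. Duplicate candidate strings are
re-recorded but scored once through a per-run cache (per-protocol cache in
Multi), since the objectives are deterministic.

### Policy network

A two-layer LSTM (hidden size 256 by default; the tests use 16–64) maps a
one-hot encoded prefix `begin + s₁…s_t` to next-token logits; probabilities
are the softmax `P(i) = exp(y_i)/Σ_j exp(y_j)`. It is implemented directly in
NumPy — batched forward pass, full backpropagation through time, Adam
(lr 1e-3, batch 128 by default), global-norm gradient clipping at 5 — which
keeps training single-threaded and bit-reproducible for a fixed seed.
Hidden size, learning rate and batch size are this package's defaults
(standard SMILES language-model settings); search behaviour is not sensitive
to them beyond proposal quality. A `UniformPolicy` over the same interface is
the no-learning baseline used by the toy-search tests.

Training data is the *partial-SMILES dataset*: all contiguous token
substrings up to `max_len` (default 35) of each corpus molecule, filtered to
fragments that parse when substituted into `C*C` **or** `C(*)C`. The OR
reading is deliberate: it keeps the empty fragment valid (`C*C` → `CC`),
which pure deletion requires. Sequences are wrapped as
`begin + fragment + terminal` and trained with teacher forcing to minimize
mean per-position cross-entropy. The corpus is split 90/10 at molecule level
*before* extraction so no fragment leaks across the split. Extraction windows
may span a whole molecule when it is shorter than `max_len`; nothing in the
procedure requires fragments to be proper substrings.

### Objectives

* `qed`: RDKit's QED; already a [0, 1] reward.
* `plogp`: `logP − SA − max(0, largest SSSR ring − 6)` from RDKit's Crippen
  logP and the Ertl–Schuffenhauer SA scorer. The ring term follows the
  penalized-logP literature's convention. The subtraction convention makes
  scores comparable with published graph-based baselines; the literal
  all-plus combination is available as `sign_convention="as-printed"`. The
  raw value is mapped to [0, 1] affinely on [−15, 15] (clipped); the bounds
  are package choices wide enough that fixture-scale molecules never clip.
* `constrained-plogp`: the plogp reward, zeroed whenever the ECFP4 (Morgan
  radius 2, 2048 bits) Tanimoto similarity to the seed falls below δ. The
  constraint is enforced in the reward itself (a hard constraint during
  search); the evaluator additionally reports unconstrained records, so
  post-hoc filtering at other thresholds remains possible.

### Single and Multi protocols

`run_single` spends the whole budget on one tree, so every product is a
one-region edit of the seed. `run_multi` restarts the tree every
`cycle_interval` steps (default 2,000 of a 10,000-step budget) from the valid
generated molecule with the highest raw score so far, ties broken by earliest
step; if no valid molecule exists yet the seed is retained with a warning.
Greedy reseeding can drift into local optima and is knowingly simple — with
one cycle the two protocols are bit-identical, and the per-cycle seed score
is non-decreasing by construction.

## Evaluation metrics

Validity = parseable outputs / all outputs. Uniqueness = distinct canonical
molecules / valid outputs. Novelty = distinct valid molecules not in the
(canonicalized) training corpus / valid outputs. Top-k means are over
distinct canonical molecules, each represented by its best raw score;
denominators of zero yield "missing", never a crash. The constrained
evaluator reports, per seed, the penalized-logP improvement of the best
qualifying product (valid, similarity ≥ δ against the *original* seed) over
the seed, that product's similarity, and success = strictly positive
improvement.

## The fixture corpus

`generate_fixture_corpus` assembles molecules from random chains, branches
and 5–6-membered (hetero)ring templates over C/N/O/S with halogen, carbonyl,
amide and nitrile decorations, validates each with the parser and
deduplicates on canonical structure; it is deterministic per (n, seed). It
emulates the *shape* of a small-molecule screening library — size range,
heteroatom content, a QED spread wider than 0.3 so optimization has headroom
— but not its realism: no stereochemistry, no charged species, no
medicinal-chemistry motifs beyond the listed decorations, and a far smaller
diversity than a real library. Tests passing at fixture scale therefore
demonstrate the *mechanics* (the search optimizes, the protocols rank as
expected, the metrics are computed correctly), not attainable property values
on real libraries; validity rates in particular are much lower with a
5-epoch, 60-molecule policy than with a fully trained one.

## Numerical choices and degenerate inputs

* Unvisited-child UCB = +∞; ties by child insertion order.
* `invalid_reward = 0`: with rewards in [0, 1], unparseable candidates are
  worst-case by construction.
* Softmax is computed with max-shift; distributions sum to 1 within 1e-9.
* Training is float64 throughout; identical seed/config/corpus give
  bit-identical weights single-threaded.
* Degenerate cases: an empty fragment is a pure deletion and is a valid
  insertable fragment; `length = 0` replacement is pure insertion;
  `start = T` appends; a one-token seed still yields three replacement nodes.
  Empty corpora, datasets with zero surviving fragments, and out-of-bounds
  replacement specs raise immediately.

## Problem sizes used by the tests and the acceptance script

Fixture corpora of 60–200 molecules, fragment windows of 6–10 tokens, LSTM
hidden sizes 16–64 trained 5–6 epochs, search budgets of 500–5,000 steps and
10 seeds per protocol. These sizes are where the package's own oracles
(brute-force enumeration of every reachable edit, closed-form update
formulas, reference chemistry implementations) remain exactly computable;
the full-scale protocol (hundreds of seeds × 10,000 steps on a 250k-molecule
corpus) uses the same code paths through the shipped presets.

## Known limitations

* No repair of invalid splice results (e.g. re-pairing ring-closure digits);
  validity is learned, not enforced.
* No bond-aware fragmentation (BRICS/RECAP); the method is deliberately
  string-level.
* Greedy next-seed selection in Multi can converge to local optima.
* The NumPy LSTM is CPU-only; at 250k-corpus scale training is slow compared
  with GPU frameworks, though the architecture is identical.
* Ring-closure digits inside fragments are inserted verbatim; a fragment that
  was valid in its source context may create or break rings in the seed.
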