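"""Outer optimization protocols and evaluation of generated molecule sets.

Two protocols wrap the tree search:

* **Single** — the seed molecule is fixed for the whole budget, so every
  product differs from the seed by exactly one contiguous token-region edit.
* **Multi** — the budget is split into cycles; after each cycle the seed is
  replaced by the best-scoring valid molecule generated so far and a fresh
  tree is built.  Repeated reseeding lets edits accumulate at multiple
  positions of the original molecule, which a single splice cannot reach.

Evaluation follows the standard generative-chemistry metrics: validity
(parseable fraction of all outputs), uniqueness (distinct canonical molecules
among the valid ones) and novelty (valid molecules absent from the training
corpus), plus the constrained-optimization summary (improvement of penalized
logP over the seed among candidates within a Tanimoto-similarity threshold,
and whether the run produced any strictly improving candidate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem

from .mcts import GenerationRecord, SearchConfig, run_search
from .policy import Policy
from .scoring import ScoreResult, plogp_score

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """Summary metrics of a generated set; fields are None when undefined
    (e.g. uniqueness with zero valid molecules)."""

    validity: Optional[float] = None
    uniqueness: Optional[float] = None
    novelty: Optional[float] = None
    top_k_mean: Optional[float] = None
    improvement: Optional[float] = None
    mean_similarity: Optional[float] = None
    success_rate: Optional[float] = None


def run_single(
    seed: str,
    model: Policy,
    reward_fn: Callable[[str], ScoreResult],
    total_steps: int,
    config: SearchConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[GenerationRecord]:
    """Fixed-seed protocol: one tree search over the whole step budget."""
    return run_search(seed, model, reward_fn, total_steps, config, rng, cycle=0)


def select_next_seed(records: Sequence[GenerationRecord]) -> str:
    """The valid record with maximal raw score; ties break by earliest step."""
    if not records:
        raise ValueError("no records to select from")
    best = None
    for rec in records:
        if not rec.valid or math.isnan(rec.raw_score):
            continue
        if best is None or rec.raw_score > best.raw_score:
            best = rec
    if best is None:
        raise ValueError("no valid record to select the next seed from")
    return best.smiles


def run_multi(
    seed: str,
    model: Policy,
    reward_fn_factory: Callable[[str], Callable[[str], ScoreResult]] | None = None,
    total_steps: int = 10_000,
    cycle_interval: int = 2_000,
    config: SearchConfig | None = None,
    rng: np.random.Generator | int | None = None,
    reward_fn: Callable[[str], ScoreResult] | None = None,
) -> list[GenerationRecord]:
    """Reseeding protocol: fresh tree every ``cycle_interval`` steps.

    Before each cycle after the first, the seed becomes the best valid
    molecule over all prior records (retained, with a warning, if none
    exists).  Either a plain ``reward_fn`` or a ``reward_fn_factory`` mapping
    the *current* seed to a reward callable may be given; use the plain form
    for objectives anchored to the original seed (e.g. similarity-constrained
    rewards) and the factory form for objectives that should re-anchor each
    cycle.  A truncated last cycle covers any remainder of the budget.
    """
    if total_steps < 1 or cycle_interval < 1:
        raise ValueError("total_steps and cycle_interval must be >= 1")
    if reward_fn is None and reward_fn_factory is None:
        raise ValueError("provide reward_fn or reward_fn_factory")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    original_seed = seed
    cache: dict = {}
    records: list[GenerationRecord] = []
    cycle = 0
    done = 0
    while done < total_steps:
        steps = min(cycle_interval, total_steps - done)
        if cycle > 0:
            try:
                seed = select_next_seed(records)
            except ValueError:
                logger.warning(
                    "cycle %d: no valid molecule yet, keeping seed %s", cycle, seed
                )
        fn = reward_fn if reward_fn is not None else reward_fn_factory(seed)
        records.extend(
            run_search(
                seed, model, fn, steps, config, rng,
                cache=cache, similarity_reference=original_seed,
                cycle=cycle, step_offset=done,
            )
        )
        done += steps
        cycle += 1
    return records


def _canonical(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def canonicalize_corpus(corpus: Sequence[str]) -> set[str]:
    """Canonical SMILES set of a training corpus (unparseable entries dropped)."""
    out = set()
    for s in corpus:
        c = _canonical(s)
        if c is not None:
            out.add(c)
    return out


def compute_metrics(
    records: Sequence[GenerationRecord],
    training_corpus: set[str],
    k: int = 3,
) -> MetricsReport:
    """Validity / uniqueness / novelty plus the mean of the k best raw scores.

    ``training_corpus`` must already be canonical SMILES (see
    :func:`canonicalize_corpus`).  Uniqueness and novelty are computed on
    canonical SMILES of the valid outputs; top-k averages over *distinct*
    valid molecules, each represented by its best raw score.
    """
    report = MetricsReport()
    total = len(records)
    valid = [r for r in records if r.valid]
    if total:
        report.validity = len(valid) / total
    if valid:
        best_by_canonical: dict[str, float] = {}
        for rec in valid:
            c = _canonical(rec.smiles)
            if c is None:  # valid flag disagreeing with the parser; count raw
                c = rec.smiles
            prev = best_by_canonical.get(c)
            if prev is None or (
                not math.isnan(rec.raw_score) and rec.raw_score > prev
            ):
                best_by_canonical[c] = rec.raw_score
        distinct = set(best_by_canonical)
        report.uniqueness = len(distinct) / len(valid)
        report.novelty = len(distinct - training_corpus) / len(valid)
        scores = sorted(
            (s for s in best_by_canonical.values() if not math.isnan(s)),
            reverse=True,
        )
        if scores:
            report.top_k_mean = float(np.mean(scores[:k]))
    return report


def constrained_eval(
    records: Sequence[GenerationRecord],
    seed: str,
    delta: float,
    sign_convention: str = "penalize",
) -> MetricsReport:
    """Constrained-optimization summary for one seed's record set.

    A record *qualifies* when it is valid and its similarity to the original
    seed is at least ``delta``.  Improvement is the penalized logP of the best
    qualifying product minus that of the seed; the run is a success when that
    improvement is strictly positive.  Similarities are taken from the records
    (they were measured against the original seed during generation).
    """
    seed_plogp = plogp_score(seed, sign_convention).raw
    best = None  # (plogp, similarity)
    plogp_cache: dict[str, float] = {}
    for rec in records:
        if not rec.valid or math.isnan(rec.similarity_to_seed):
            continue
        if rec.similarity_to_seed < delta:
            continue
        if rec.smiles not in plogp_cache:
            try:
                plogp_cache[rec.smiles] = plogp_score(rec.smiles, sign_convention).raw
            except ValueError:
                continue
        value = plogp_cache[rec.smiles]
        if best is None or value > best[0]:
            best = (value, rec.similarity_to_seed)
    report = MetricsReport()
    if best is not None:
        report.improvement = best[0] - seed_plogp
        report.mean_similarity = best[1]
        report.success_rate = 1.0 if report.improvement > 0 else 0.0
    else:
        report.success_rate = 0.0
    return report
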