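"""Molecular objective functions and reward normalization.

Two standard objectives drive the search:

* **QED** — the quantitative estimate of drug-likeness, already in [0, 1].
* **Penalized logP** — the octanol–water partition coefficient combined with
  the Ertl–Schuffenhauer synthetic-accessibility (SA) score and a penalty for
  rings larger than six atoms.  By convention in the property-optimization
  literature the two latter terms are *subtracted*,

      plogp = logP − SA − max(0, largest ring − 6),

  and that is the default here; ``sign_convention="as-printed"`` adds them
  instead for anyone who wants the literal three-term sum.

The tree policy (UCB) assumes rewards in [0, 1], so unbounded raw scores are
passed through an affine clip ``normalize_reward``.  The similarity-constrained
objective zeroes the reward of any candidate whose ECFP4 Tanimoto similarity to
the seed falls below a threshold δ.
"""

from __future__ import annotations

import math
import os
import sys
from dataclasses import dataclass, field
from typing import Callable

from rdkit import Chem
from rdkit.Chem import QED, Crippen, DataStructs, RDConfig
from rdkit.Chem import rdFingerprintGenerator

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module, needs the path above)

# ECFP4 = Morgan fingerprint of radius 2.
_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

# Default affine-normalization window for penalized logP; wide enough that the
# fixture-scale molecules never clip, configurable for other corpora.
PLOGP_BOUNDS = (-15.0, 15.0)


@dataclass
class ScoreResult:
    """A raw objective value, its named components, and the [0,1] tree reward."""

    raw: float
    normalized: float
    components: dict[str, float] = field(default_factory=dict)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol


def normalize_reward(raw: float, lo: float, hi: float) -> float:
    """Affine map of [lo, hi] onto [0, 1], clipped outside; monotone in raw."""
    if lo >= hi:
        raise ValueError("normalization requires lo < hi")
    return min(1.0, max(0.0, (raw - lo) / (hi - lo)))


def qed_score(smiles: str) -> ScoreResult:
    """Drug-likeness in [0, 1]; the raw value is already a valid tree reward."""
    raw = QED.qed(_mol(smiles))
    return ScoreResult(raw=raw, normalized=raw, components={"qed": raw})


def ring_penalty(mol: Chem.Mol) -> float:
    """max(0, largest ring size − 6); zero for acyclic molecules."""
    rings = mol.GetRingInfo().AtomRings()
    if not rings:
        return 0.0
    return float(max(0, max(len(r) for r in rings) - 6))


def plogp_score(
    smiles: str,
    sign_convention: str = "penalize",
    bounds: tuple[float, float] = PLOGP_BOUNDS,
) -> ScoreResult:
    """Penalized logP with its three components.

    ``sign_convention="penalize"`` (default) subtracts the SA score and ring
    penalty from logP; ``"as-printed"`` adds all three terms.
    """
    mol = _mol(smiles)
    logp = Crippen.MolLogP(mol)
    sa = sascorer.calculateScore(mol)
    ring = ring_penalty(mol)
    if sign_convention == "penalize":
        raw = logp - sa - ring
    elif sign_convention == "as-printed":
        raw = logp + sa + ring
    else:
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    return ScoreResult(
        raw=raw,
        normalized=normalize_reward(raw, *bounds),
        components={"logp": logp, "sa": sa, "ring_penalty": ring},
    )


def fingerprint(smiles: str):
    """ECFP4-equivalent bit fingerprint (Morgan, radius 2, 2048 bits)."""
    return _MORGAN.GetFingerprint(_mol(smiles))


def tanimoto_similarity(a: str, b: str) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over ECFP4 bit sets."""
    return DataStructs.TanimotoSimilarity(fingerprint(a), fingerprint(b))


def constrained_reward_fn(
    seed: str,
    delta: float,
    invalid_reward: float = 0.0,
    sign_convention: str = "penalize",
    bounds: tuple[float, float] = PLOGP_BOUNDS,
) -> Callable[[str], ScoreResult]:
    """Similarity-constrained penalized-logP objective.

    Candidates whose ECFP4 Tanimoto similarity to ``seed`` is below ``delta``
    receive the invalid reward; all failures (unparseable candidates included)
    map there too.  ``delta=0`` reduces to the plain penalized-logP reward.
    """
    seed_fp = fingerprint(seed)

    def reward(candidate: str) -> ScoreResult:
        try:
            cand_fp = fingerprint(candidate)
        except ValueError:
            return ScoreResult(raw=math.nan, normalized=invalid_reward)
        sim = DataStructs.TanimotoSimilarity(seed_fp, cand_fp)
        result = plogp_score(candidate, sign_convention, bounds)
        result.components["similarity"] = sim
        if sim < delta:
            result.normalized = invalid_reward
        return result

    return reward


# Score plug-in registry: name -> factory(seed, **options) -> callable.
def _qed_factory(seed: str, **_: object) -> Callable[[str], ScoreResult]:
    return qed_score


def _plogp_factory(
    seed: str, sign_convention: str = "penalize", **_: object
) -> Callable[[str], ScoreResult]:
    return lambda s: plogp_score(s, sign_convention=sign_convention)


def _constrained_factory(
    seed: str, delta: float = 0.4, sign_convention: str = "penalize", **_: object
) -> Callable[[str], ScoreResult]:
    return constrained_reward_fn(seed, delta, sign_convention=sign_convention)


SCORES: dict[str, Callable[..., Callable[[str], ScoreResult]]] = {
    "qed": _qed_factory,
    "plogp": _plogp_factory,
    "constrained-plogp": _constrained_factory,
}


def register_score(name: str, factory: Callable[..., Callable[[str], ScoreResult]]):
    """Register a custom objective; any SMILES -> ScoreResult callable works."""
    SCORES[name] = factory


def get_score(name: str, seed: str, **options) -> Callable[[str], ScoreResult]:
    if name not in SCORES:
        raise KeyError(f"unknown score {name!r}; known: {sorted(SCORES)}")
    return SCORES[name](seed, **options)
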