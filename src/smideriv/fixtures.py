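"""Deterministic generator of a small drug-like-ish SMILES corpus.

Training the next-token policy needs a corpus of valid molecules; real runs
use a library such as ZINC, but tests and examples use this rule-based
generator so nothing has to be downloaded.  Molecules are assembled from
chains, branches and 5–6-membered (hetero)ring templates over C/N/O/S plus
halogens and carbonyl/amide decorations, then verified with the chemistry
parser and deduplicated on canonical structure.  The same (n, seed) always
yields the same corpus.

The assembly rules are biased toward small, partly aromatic, lightly
functionalised molecules so that the corpus spans a wide band of QED values —
wide enough that property optimization starting from a poor seed has headroom.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

from .smiles import is_valid_smiles

_PLAIN_ATOMS = ["C", "C", "C", "C", "C", "N", "N", "O", "O", "S"]
_SUBSTITUENTS = ["F", "Cl", "Br", "C", "O", "N", "C(=O)O", "C(=O)N", "C#N", "OC"]
# '{}' marks an optional substitution point filled by a chain.
_RING_TEMPLATES = [
    "c1ccc({})cc1",
    "c1ccccc1",
    "c1ccncc1",
    "c1cc({})ncc1",
    "c1ccoc1",
    "c1ccsc1",
    "C1CCCCC1",
    "C1CCN({})CC1",
    "C1CCOC1",
    "C1CCNC1",
    "C1CCCN({})C1",
]
_LINKERS = ["", "C", "CC", "O", "N", "C(=O)", "C(=O)N", "S"]


def _chain(rng: np.random.Generator, max_atoms: int = 6) -> str:
    parts: list[str] = []
    for i in range(int(rng.integers(1, max_atoms + 1))):
        if i > 0 and rng.random() < 0.12:
            parts.append("=")
        parts.append(_PLAIN_ATOMS[int(rng.integers(len(_PLAIN_ATOMS)))])
        if rng.random() < 0.25:
            parts.append(f"({_SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]})")
    return "".join(parts)


def _candidate(rng: np.random.Generator) -> str:
    pieces: list[str] = []
    n_pieces = int(rng.integers(1, 3 + (rng.random() < 0.3)))
    for i in range(n_pieces):
        if i > 0:
            pieces.append(_LINKERS[int(rng.integers(len(_LINKERS)))])
        if rng.random() < 0.55:
            template = _RING_TEMPLATES[int(rng.integers(len(_RING_TEMPLATES)))]
            if "{}" in template:
                fill = _chain(rng, 3) if rng.random() < 0.7 else ""
                template = (
                    template.format(fill) if fill
                    else template.replace("({})", "").replace("{}", "")
                )
            pieces.append(template)
        else:
            pieces.append(_chain(rng))
    return "".join(pieces)


def generate_fixture_corpus(n: int, seed: int = 0, max_attempts_per_molecule: int = 400) -> list[str]:
    """Generate ``n`` distinct valid SMILES, deterministically for a seed.

    Raises ``RuntimeError`` if the attempt budget is exhausted before ``n``
    distinct molecules are found (only plausible for very large n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    corpus: list[str] = []
    seen: set[str] = set()
    attempts = 0
    budget = n * max_attempts_per_molecule
    while len(corpus) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not assemble {n} distinct molecules in {budget} attempts"
            )
        attempts += 1
        smiles = _candidate(rng)
        if not is_valid_smiles(smiles):
            continue
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
        if canonical in seen:
            continue
        seen.add(canonical)
        corpus.append(smiles)
    return corpus


def split_corpus(
    corpus: list[str], train_fraction: float = 0.9, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Molecule-level train/validation split (fragments never leak across)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_train = max(1, int(round(train_fraction * len(corpus))))
    n_train = min(n_train, len(corpus) - 1) if len(corpus) > 1 else n_train
    train = [corpus[i] for i in order[:n_train]]
    valid = [corpus[i] for i in order[n_train:]]
    return train, valid
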