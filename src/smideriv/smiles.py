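"""SMILES string primitives: tokenization, partial-string extraction and splicing.

The generator edits molecules purely at the string level: a contiguous run of
seed tokens is deleted and a generated partial SMILES is inserted in its place.
A "token" here is what a chemist would call one SMILES unit — a two-letter
element (``Cl``, ``Br``), a bracket atom (``[nH]``, ``[O-]``), a two-digit ring
closure (``%12``) or a single character.  Operating on tokens rather than raw
characters guarantees an edit can never split ``Cl`` into ``C`` + ``l``.

Partial SMILES are generally not parseable molecules on their own.  A fragment
is considered *insertable* when pasting it into at least one of the two probe
contexts ``C*C`` or ``C(*)C`` (``*`` marks the insertion point) yields a string
the chemistry parser accepts.  The training corpus for the next-token policy is
the set of insertable fragments extracted exhaustively from a corpus of full
SMILES.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparseable candidate; candidate strings being
# invalid is the normal case here, not an error.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

BEGIN_TOKEN = "<bos>"
TERMINAL_TOKEN = "<eos>"

# Multi-character units first so the alternation prefers them.
_TOKEN_RE = re.compile(
    r"(\[[^\[\]]+\]|Br|Cl|%\d\d|[BCNOPSFIbcnops]|[0-9]|[-=#$:/\\+().@*])"
)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens.

    The input need not be chemically valid; only the lexical alphabet is
    checked.  Raises ``ValueError`` on characters outside the SMILES alphabet.
    """
    tokens: list[str] = []
    pos = 0
    n = len(smiles)
    while pos < n:
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise ValueError(
                f"character {smiles[pos]!r} at position {pos} is not part of "
                f"the SMILES alphabet: {smiles!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Concatenate tokens back into a SMILES string (inverse of :func:`tokenize`)."""
    return "".join(tokens)


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token inventory with begin/terminal sentinels.

    ``tokens`` lists every token including the two sentinels; ``index_of`` is a
    bijection onto ``0..V-1`` in list order.
    """

    tokens: tuple[str, ...]
    begin_token: str = BEGIN_TOKEN
    terminal_token: str = TERMINAL_TOKEN
    index_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be distinct")
        for sentinel in (self.begin_token, self.terminal_token):
            if sentinel not in self.tokens:
                raise ValueError(f"sentinel {sentinel!r} missing from vocabulary")
        if self.begin_token == self.terminal_token:
            raise ValueError("begin and terminal sentinels must differ")
        object.__setattr__(
            self, "index_of", {t: i for i, t in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def chemical_tokens(self) -> tuple[str, ...]:
        return tuple(
            t for t in self.tokens if t not in (self.begin_token, self.terminal_token)
        )

    @classmethod
    def from_fragments(cls, fragments: Iterable[str]) -> "TokenVocabulary":
        """Build a vocabulary from the distinct tokens of a fragment collection.

        Chemical tokens are sorted for determinism; sentinels occupy the last
        two slots.
        """
        seen: set[str] = set()
        for frag in fragments:
            seen.update(tokenize(frag))
        ordered = tuple(sorted(seen)) + (BEGIN_TOKEN, TERMINAL_TOKEN)
        return cls(tokens=ordered)


def default_parser(smiles: str) -> bool:
    """The chemistry-parser contract: does RDKit accept the string as a molecule?"""
    try:
        return Chem.MolFromSmiles(smiles) is not None
    except Exception:
        return False


def is_valid_smiles(smiles: str, parser: Callable[[str], bool] = default_parser) -> bool:
    """True iff the parser accepts the string; every failure mode maps to False."""
    try:
        return bool(parser(smiles))
    except Exception:
        return False


# The two probe contexts; '*' marks where the fragment is pasted in.
PARTIAL_CONTEXTS = ("C*C", "C(*)C")


def is_valid_partial(
    fragment: str, parser: Callable[[str], bool] = default_parser
) -> bool:
    """Insertion-context validity filter for partial SMILES.

    A fragment is insertable if substituting it for ``*`` in at least one of
    ``C*C`` / ``C(*)C`` parses.  The OR semantics keep the empty fragment valid
    (``C*C`` -> ``CC``), which pure deletion of seed tokens requires.
    """
    for context in PARTIAL_CONTEXTS:
        try:
            if parser(context.replace("*", fragment)):
                return True
        except Exception:
            continue
    return False


def extract_partials(smiles: str, max_len: int) -> set[str]:
    """All distinct contiguous token-substrings of length 1..max_len.

    Raises ``ValueError`` if the input is not a valid molecule or max_len < 1.
    """
    if max_len < 1:
        raise ValueError("max_len must be a positive integer")
    if not is_valid_smiles(smiles):
        raise ValueError(f"not a valid SMILES molecule: {smiles!r}")
    tokens = tokenize(smiles)
    out: set[str] = set()
    T = len(tokens)
    for start in range(T):
        for stop in range(start + 1, min(start + max_len, T) + 1):
            out.add(detokenize(tokens[start:stop]))
    return out


@dataclass
class PartialSmilesDataset:
    """Deduplicated insertable fragments extracted from a corpus.

    ``fragments`` is stored sorted for reproducibility; ``filter_stats`` counts
    the extracted fragments, the retained (insertable) ones, and corpus lines
    skipped as unparseable.
    """

    fragments: tuple[str, ...]
    source_count: int
    filter_stats: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.fragments)) != len(self.fragments):
            raise ValueError("fragments must be deduplicated")

    def __len__(self) -> int:
        return len(self.fragments)


def build_partial_dataset(
    corpus: Sequence[str],
    max_len: int = 35,
    parser: Callable[[str], bool] = default_parser,
) -> PartialSmilesDataset:
    """Extract, filter and deduplicate partial SMILES from a corpus.

    Unparseable corpus entries are skipped with a log message.  Raises if the
    corpus is empty or no fragment survives the insertion-context filter.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    extracted: set[str] = set()
    skipped = 0
    processed = 0
    for line in corpus:
        try:
            extracted |= extract_partials(line, max_len)
            processed += 1
        except ValueError:
            skipped += 1
            logger.warning("skipping unparseable corpus entry: %r", line)
    retained = tuple(sorted(f for f in extracted if is_valid_partial(f, parser)))
    if not retained:
        raise ValueError("no fragment survived the insertion-context filter")
    return PartialSmilesDataset(
        fragments=retained,
        source_count=processed,
        filter_stats={
            "extracted": len(extracted),
            "retained": len(retained),
            "skipped_lines": skipped,
        },
    )


@dataclass(frozen=True)
class ReplacementSpec:
    """Which contiguous token span of the seed is deleted before insertion.

    ``start`` is a 0-based token index; ``length`` tokens are removed
    (``length=0`` means pure insertion at ``start``).
    """

    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.length < 0:
            raise ValueError("start and length must be non-negative")


def splice(seed: str, spec: ReplacementSpec, fragment: str) -> str:
    """Delete seed tokens [start, start+length) and insert ``fragment`` there.

    Pure string surgery at token level; the result is not guaranteed to be a
    valid molecule.  Raises ``ValueError`` when the spec exceeds the seed's
    token count.
    """
    tokens = tokenize(seed)
    if spec.start > len(tokens) or spec.start + spec.length > len(tokens):
        raise ValueError(
            f"replacement {spec} out of bounds for seed of {len(tokens)} tokens"
        )
    return (
        detokenize(tokens[: spec.start])
        + fragment
        + detokenize(tokens[spec.start + spec.length :])
    )
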