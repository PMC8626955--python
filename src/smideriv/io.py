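"""File formats: .smi corpora, fragment-dataset artifacts, record tables, config.

Everything is plain text: SMILES files are one molecule per line with an
optional whitespace-separated identifier, generation records are CSV, the
fragment dataset is a text file with a JSON sidecar, and run configuration is
versioned YAML with fail-fast handling of unknown keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .mcts import GenerationRecord
from .smiles import PartialSmilesDataset, ReplacementSpec

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1

RECORD_COLUMNS = [
    "step", "cycle", "replacement_start", "replacement_length",
    "fragment", "smiles", "valid", "raw_score", "normalized_reward",
    "similarity_to_seed",
]


def read_smiles_file(path) -> list[tuple[str, Optional[str]]]:
    """Read a .smi file: ``SMILES [identifier]`` per line.

    Blank lines and lines starting with ``#`` are skipped (counted in a log
    message); the order of molecules is preserved.
    """
    entries: list[tuple[str, Optional[str]]] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                skipped += 1
                continue
            parts = line.split(None, 1)
            entries.append((parts[0], parts[1].strip() if len(parts) > 1 else None))
    if skipped:
        logger.info("read %s: %d entries, %d blank/comment lines skipped",
                    path, len(entries), skipped)
    return entries


def write_smiles_file(path, smiles: Sequence[str], ids: Optional[Sequence[str]] = None):
    with open(path, "w") as fh:
        for i, s in enumerate(smiles):
            if ids is not None:
                fh.write(f"{s}\t{ids[i]}\n")
            else:
                fh.write(f"{s}\n")


def file_fingerprint(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ------------------------------------------------------------ fragment dataset


def save_partial_dataset(dataset: PartialSmilesDataset, path, params: dict | None = None):
    """One fragment per line, plus a ``<path>.json`` sidecar with the stats."""
    path = Path(path)
    with open(path, "w") as fh:
        for frag in dataset.fragments:
            fh.write(frag + "\n")
    sidecar = {
        "source_count": dataset.source_count,
        "filter_stats": dataset.filter_stats,
        "params": params or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_partial_dataset(path) -> PartialSmilesDataset:
    path = Path(path)
    fragments = tuple(
        line.rstrip("\n") for line in path.read_text().splitlines()
    )
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        return PartialSmilesDataset(
            fragments=fragments,
            source_count=sidecar.get("source_count", 0),
            filter_stats=sidecar.get("filter_stats", {}),
        )
    return PartialSmilesDataset(fragments=fragments, source_count=0, filter_stats={})


# ------------------------------------------------------------------- records


def records_to_frame(records: Sequence[GenerationRecord]) -> pd.DataFrame:
    rows = [
        {
            "step": r.step,
            "cycle": r.cycle,
            "replacement_start": r.replacement.start,
            "replacement_length": r.replacement.length,
            "fragment": r.fragment,
            "smiles": r.smiles,
            "valid": r.valid,
            "raw_score": r.raw_score,
            "normalized_reward": r.normalized_reward,
            "similarity_to_seed": r.similarity_to_seed,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: Sequence[GenerationRecord], path) -> None:
    """Lossless CSV round-trip of every record field."""
    records_to_frame(records).to_csv(path, index=False)


def load_records(path) -> list[GenerationRecord]:
    df = pd.read_csv(
        path, keep_default_na=False,
        dtype={"fragment": str, "smiles": str},
        na_values={"raw_score": [""], "similarity_to_seed": [""],
                   "normalized_reward": [""]},
    )
    out: list[GenerationRecord] = []
    for row in df.itertuples(index=False):
        out.append(
            GenerationRecord(
                smiles=row.smiles,
                valid=str(row.valid) in ("True", "true", "1"),
                raw_score=float(row.raw_score) if row.raw_score == row.raw_score else math.nan,
                normalized_reward=float(row.normalized_reward),
                step=int(row.step),
                cycle=int(row.cycle),
                replacement=ReplacementSpec(
                    start=int(row.replacement_start),
                    length=int(row.replacement_length),
                ),
                fragment=row.fragment,
                similarity_to_seed=(
                    float(row.similarity_to_seed)
                    if row.similarity_to_seed == row.similarity_to_seed
                    else math.nan
                ),
            )
        )
    return out


# -------------------------------------------------------------------- config


@dataclass
class RunConfig:
    """Full run configuration; every field has a documented default.

    Round-trips losslessly through YAML; loading rejects unknown keys.
    """

    config_version: int = CONFIG_VERSION
    # objective
    score: str = "qed"              # registered score name
    delta: float = 0.4              # similarity threshold (constrained score)
    plogp_sign: str = "penalize"    # 'penalize' (logP - SA - ring) | 'as-printed'
    # search
    steps: int = 10_000             # total simulation budget per seed
    mode: str = "multi"             # 'single' | 'multi'
    cycle_interval: int = 2_000     # reseeding period of the multi protocol
    c_p: float = 1.0 / math.sqrt(2.0)
    expansion_samples: int = 10
    max_fragment_len: int = 20      # tokens, generated fragments
    max_removal_len: int = 10       # tokens, deleted seed span
    invalid_reward: float = 0.0
    # training
    dataset_max_fragment_len: int = 35
    hidden_size: int = 256
    epochs: int = 20
    batch_size: int = 128
    learning_rate: float = 1e-3
    train_fraction: float = 0.9
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.config_version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {cfg.config_version}")
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

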