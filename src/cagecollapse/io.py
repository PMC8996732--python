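"""Dataset readers/writers and run provenance.

Dataset CSV schema: ``cage_id, bb_smiles, linker_smiles, reaction, label``
(UTF-8, comma-separated; the label column may be empty for unlabelled
records).  Descriptor CSVs carry semicolon-separated window-diameter
lists inside a single column so a dataset stays one file.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Sequence

import pandas as pd

from .train_eval import LABELS, REACTION_FAMILIES, CageRecord

__all__ = [
    "DATASET_COLUMNS",
    "DatasetError",
    "DatasetLoadResult",
    "read_dataset",
    "load_dataset",
    "write_dataset",
    "write_provenance",
]

DATASET_COLUMNS = ("cage_id", "bb_smiles", "linker_smiles", "reaction", "label")


class DatasetError(ValueError):
    """Schema or row-level validation failure in a dataset file."""


@dataclass
class DatasetLoadResult:
    """Validated records plus a row-numbered report of rejected rows."""

    records: list[CageRecord] = field(default_factory=list)
    errors: list[tuple[int, str]] = field(default_factory=list)


def load_dataset(path: str | Path, strict: bool = False) -> DatasetLoadResult:
    """Read and validate a dataset CSV.

    Malformed rows are collected with their (1-based, data) row numbers;
    in strict mode the first malformed row aborts the read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetError(
            f"dataset {path} missing required columns: {sorted(missing)}"
        )
    result = DatasetLoadResult()
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            label = row.label.strip() or None
            if label is not None and label not in LABELS:
                raise ValueError(f"unknown label {label!r}")
            if row.reaction not in REACTION_FAMILIES:
                raise ValueError(f"unknown reaction {row.reaction!r}")
            if not row.bb_smiles or not row.linker_smiles:
                raise ValueError("empty SMILES field")
            result.records.append(
                CageRecord(
                    bb_smiles=row.bb_smiles,
                    linker_smiles=row.linker_smiles,
                    reaction=row.reaction,
                    label=label,
                    cage_id=row.cage_id,
                )
            )
        except ValueError as exc:
            if strict:
                raise DatasetError(f"row {row_no}: {exc}") from exc
            result.errors.append((row_no, str(exc)))
    return result


def read_dataset(path: str | Path, strict: bool = False) -> list[CageRecord]:
    """Thin wrapper over :func:`load_dataset` returning only the records."""
    return load_dataset(path, strict=strict).records


def write_dataset(records: Sequence[CageRecord], path: str | Path) -> None:
    """Write records to the dataset CSV schema (round-trip stable)."""
    df = pd.DataFrame(
        [
            {
                "cage_id": r.cage_id,
                "bb_smiles": r.bb_smiles,
                "linker_smiles": r.linker_smiles,
                "reaction": r.reaction,
                "label": r.label or "",
            }
            for r in records
        ],
        columns=list(DATASET_COLUMNS),
    )
    df.to_csv(path, index=False)


def write_provenance(
    out_path: str | Path, config: dict, seeds: dict | None = None
) -> Path:
    """Write a provenance JSON (config hash, seeds, versions) next to an output."""
    out_path = Path(out_path)
    blob = json.dumps(config, sort_keys=True, default=str)
    try:
        version = metadata.version("cagecollapse")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    record = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": seeds or {},
        "versions": {
            "cagecollapse": version,
            "python": platform.python_version(),
        },
    }
    prov_path = out_path.with_suffix(out_path.suffix + ".provenance.json")
    prov_path.write_text(json.dumps(record, indent=2, default=str))
    return prov_path
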