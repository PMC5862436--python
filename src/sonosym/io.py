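"""Readers, writers and run manifests.

All tables are UTF-8, tab-delimited, header-required; IPA strings are kept
in NFC.  Factors that a modality does not manipulate are stored as empty
cells and read back as ``None``.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .encoding import META_COLUMNS, OnomatopoeiaRecord

TRANSCRIPTION_COLUMNS = META_COLUMNS  # speaker..sound, ipa


class SchemaError(ValueError):
    """Raised when an input table does not match the documented schema."""


def write_transcriptions(records: Iterable[OnomatopoeiaRecord], path: str | Path) -> None:
    rows = [
        {
            "speaker": r.speaker,
            "modality": r.modality,
            "movement": r.movement,
            "shape": r.shape or "",
            "size": r.size or "",
            "sound": r.sound or "",
            "ipa": unicodedata.normalize("NFC", r.ipa),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(TRANSCRIPTION_COLUMNS)).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_transcriptions(path: str | Path) -> list[OnomatopoeiaRecord]:
    """Read a transcription table into validated records.

    Raises :class:`SchemaError` naming missing columns, and aggregates
    row-level validation failures into one error listing the bad rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    if missing := set(TRANSCRIPTION_COLUMNS) - set(df.columns):
        raise SchemaError(f"transcription table is missing columns: {sorted(missing)}")
    records, errors = [], []
    for idx, row in df.iterrows():
        try:
            records.append(
                OnomatopoeiaRecord(
                    speaker=row["speaker"],
                    modality=row["modality"],
                    movement=row["movement"],
                    shape=row["shape"] or None,
                    size=row["size"] or None,
                    sound=row["sound"] or None,
                    ipa=unicodedata.normalize("NFC", row["ipa"]),
                )
            )
        except ValueError as exc:
            errors.append(f"row {idx + 2}: {exc}")
    if errors:
        raise SchemaError(
            f"{len(errors)} invalid row(s):\n" + "\n".join(errors[:20])
        )
    return records


def modality_counts(records: Iterable[OnomatopoeiaRecord]) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in records:
        out[r.modality] = out.get(r.modality, 0) + 1
    return out


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a stage: config, seeds, input digests."""

    stage: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: list = field(default_factory=list)
    package_version: str = ""
    timings: dict = field(default_factory=dict)
    created: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
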