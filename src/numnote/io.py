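"""Note / label table I/O.

Notes travel as a two-column CSV (note_id, text) with a separate label CSV
(note_id, label in {0,1}); tokenized output is JSON-lines, one record per
note with its id, tokens and numeric mentions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "NoteRecord",
    "read_notes",
    "write_notes",
    "read_labels",
    "write_labels",
    "write_tokenized_jsonl",
]


@dataclass
class NoteRecord:
    """One clinical note: id, raw text and binary outcome label."""

    note_id: str
    text: str
    label: int | None = None


def read_notes(notes_path, labels_path=None) -> list[NoteRecord]:
    df = pd.read_csv(notes_path, dtype={"note_id": str})
    labels = None
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, dtype={"note_id": str})
        labels = dict(zip(ldf["note_id"], ldf["label"].astype(int)))
    out = []
    for _, row in df.iterrows():
        lab = labels.get(row["note_id"]) if labels is not None else None
        out.append(NoteRecord(note_id=row["note_id"], text=row["text"], label=lab))
    return out


def write_notes(records: Sequence[NoteRecord], notes_path) -> None:
    pd.DataFrame(
        {"note_id": [r.note_id for r in records],
         "text": [r.text for r in records]}
    ).to_csv(notes_path, index=False)


def read_labels(labels_path) -> dict[str, int]:
    df = pd.read_csv(labels_path, dtype={"note_id": str})
    return dict(zip(df["note_id"], df["label"].astype(int)))


def write_labels(records: Sequence[NoteRecord], labels_path) -> None:
    pd.DataFrame(
        {"note_id": [r.note_id for r in records],
         "label": [int(r.label) for r in records]}
    ).to_csv(labels_path, index=False)


def write_tokenized_jsonl(path, records) -> None:
    """records: iterable of (note_id, tokens, mentions) triples."""
    with Path(path).open("w") as fh:
        for note_id, tokens, mentions in records:
            fh.write(json.dumps({
                "note_id": note_id,
                "tokens": list(tokens),
                "mentions": [
                    {"position": m.position, "value": m.value,
                     "keyword": m.keyword, "in_context": m.in_context}
                    for m in mentions
                ],
            }) + "\n")
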