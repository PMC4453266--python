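"""Corpus I/O: document data model, tokenization, and score tables.

A corpus is a directory of UTF-8 ``.txt`` files, one document per file, with
an optional CSV label table (``doc_id,label``) assigning each document to the
``positive`` or ``comparison`` group.  Decoding errors are hard failures:
silently replacing bytes would corrupt the word frequencies everything
downstream is built on.
"""

from __future__ import annotations

import csv
import re
import sys
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "Token",
    "Document",
    "Corpus",
    "CorpusError",
    "tokenize",
    "load_corpus",
    "write_corpus",
    "write_scores",
    "log",
]

VALID_LABELS = ("positive", "comparison")
POS_TAGS = ("NOUN", "VERB", "ADJ", "OTHER")

# Tokens are maximal runs of letters with optional internal apostrophes;
# digits, punctuation and everything else separate.
_WORD_RE = re.compile(r"[^\W\d_]+(?:'[^\W\d_]+)*")


class CorpusError(ValueError):
    """Raised for malformed corpora, label tables or score tables."""


def log(message: str) -> None:
    """Write a timestamped run-log line to standard error."""
    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    print(f"[{stamp}] {message}", file=sys.stderr)


@dataclass(frozen=True)
class Token:
    """One token of a document.

    ``pos`` is one of NOUN/VERB/ADJ/OTHER and starts as OTHER until a tagger
    fills it in; ``position`` is the 0-based index in the token stream.
    """

    surface: str
    normalized: str
    pos: str = "OTHER"
    position: int = 0

    def with_pos(self, pos: str) -> "Token":
        if pos not in POS_TAGS:
            raise CorpusError(f"invalid POS tag {pos!r}")
        return replace(self, pos=pos)


@dataclass
class Document:
    """One unit of text with identity, optional group label and metadata."""

    doc_id: str
    raw_text: str
    label: str | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.raw_text.strip():
            raise CorpusError(f"document {self.doc_id!r} is empty")
        if self.label is not None and self.label not in VALID_LABELS:
            raise CorpusError(
                f"document {self.doc_id!r} has label {self.label!r}; "
                f"expected one of {VALID_LABELS}"
            )


@dataclass
class Corpus:
    """An ordered collection of documents with unique ids."""

    documents: list[Document]

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusError(f"duplicate doc_id(s): {dupes}")

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    @property
    def labels(self) -> pd.Series:
        """Label per document as a pandas Series indexed by doc_id."""
        return pd.Series(
            {d.doc_id: d.label for d in self.documents}, name="label", dtype=object
        )

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __len__(self) -> int:
        return self.n_docs

    def __getitem__(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)


def tokenize(raw_text: str) -> list[Token]:
    """Split text into :class:`Token` objects.

    Pure and deterministic: tokens are maximal runs of letters/apostrophes,
    lowercased into ``normalized``; punctuation and digits separate.  An
    empty string yields an empty list.
    """
    return [
        Token(
            surface=m.group(0),
            normalized=m.group(0).casefold(),
            pos="OTHER",
            position=i,
        )
        for i, m in enumerate(_WORD_RE.finditer(raw_text))
    ]


def load_corpus(
    directory_path: str | Path, labels_table: str | Path | None = None
) -> Corpus:
    """Load every ``.txt`` file in a directory as one document.

    Documents are ordered lexicographically by doc_id (= file stem).  If a
    label table is given it must be a CSV with columns ``doc_id,label``;
    ids in the table that have no matching file are an error.
    """
    directory = Path(directory_path)
    files = sorted(directory.glob("*.txt"), key=lambda p: p.stem)
    if not files:
        raise CorpusError(f"no .txt files found in {directory}")

    labels: dict[str, str] = {}
    meta: dict[str, dict[str, str]] = {}
    if labels_table is not None:
        table = pd.read_csv(labels_table, dtype=str)
        for col in ("doc_id", "label"):
            if col not in table.columns:
                raise CorpusError(f"label table missing required column {col!r}")
        stems = {f.stem for f in files}
        extra_cols = [c for c in table.columns if c not in ("doc_id", "label")]
        for _, row in table.iterrows():
            doc_id = row["doc_id"]
            if doc_id not in stems:
                raise CorpusError(
                    f"label table references doc_id {doc_id!r} with no matching .txt file"
                )
            labels[doc_id] = row["label"]
            meta[doc_id] = {c: row[c] for c in extra_cols if pd.notna(row[c])}

    documents = [
        Document(
            doc_id=f.stem,
            raw_text=f.read_text(encoding="utf-8"),
            label=labels.get(f.stem),
            meta=meta.get(f.stem, {}),
        )
        for f in files
    ]
    log(f"loaded {len(documents)} documents from {directory}")
    return Corpus(documents)


def write_corpus(
    corpus: Corpus,
    directory_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Write a corpus as one ``.txt`` per document plus an optional labels CSV."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in corpus:
        (directory / f"{doc.doc_id}.txt").write_text(doc.raw_text, encoding="utf-8")
    if labels_path is not None:
        with open(labels_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["doc_id", "label"])
            for doc in sorted(corpus, key=lambda d: d.doc_id):
                writer.writerow([doc.doc_id, doc.label or ""])


def _format_cell(value) -> str:
    if value is None or (isinstance(value, float) and value != value):
        return ""  # undefined score cell
    return format(float(value), ".6g")


def write_scores(table, out_path: str | Path) -> None:
    """Write a score matrix as CSV with header ``doc_id,label,<traits...>``.

    Rows are sorted by doc_id and floats rendered with 6 significant digits,
    so re-writing the same table produces a byte-identical file.  Undefined
    cells are written empty.  ``table`` may be a
    :class:`~traitspace.trait_scoring.ScoreMatrix` or an equivalent
    DataFrame with a ``doc_id`` column, a ``label`` column and one column
    per trait.
    """
    if hasattr(table, "to_frame") and not isinstance(table, pd.DataFrame):
        frame = table.to_frame()
    else:
        frame = table
    if frame is None or len(frame) == 0:
        raise CorpusError("refusing to write an empty score table")
    frame = frame.sort_values("doc_id")
    trait_cols = [c for c in frame.columns if c not in ("doc_id", "label")]
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["doc_id", "label"] + trait_cols)
        for _, row in frame.iterrows():
            label = row.get("label")
            if label is None or (isinstance(label, float) and label != label):
                label = ""
            writer.writerow(
                [row["doc_id"], label] + [_format_cell(row[c]) for c in trait_cols]
            )
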