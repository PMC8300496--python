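"""Corpus input/output.

Reads documents (one text unit each, typically an abstract) from plain-text
files, delimited tables and RIS bibliographic exports into a uniform
:class:`Corpus`, and persists extracted link tables as CSV.

Text is always decoded as UTF-8; anything else is rejected rather than
guessed, so a corpus read twice is byte-identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

import pandas as pd

from .errors import (
    EncodingError,
    InputError,
    RISParseError,
    SchemaError,
    UniquenessError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .extraction import CausalLink

LINK_COLUMNS = (
    "doc_id",
    "sentence_index",
    "driver",
    "keyword",
    "target",
    "weight",
    "voice",
    "sentence_text",
)


@dataclass(frozen=True)
class Document:
    """One text unit (e.g. an abstract) with a stable identifier."""

    doc_id: str
    text: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise UniquenessError("doc_id must be non-empty")


@dataclass(frozen=True)
class Corpus:
    """Ordered collection of documents with unique ids."""

    documents: tuple[Document, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "documents", tuple(self.documents))
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise UniquenessError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]


def _read_utf8(path: Path) -> str:
    try:
        data = path.read_bytes()
    except FileNotFoundError as exc:
        raise InputError(f"input path does not exist: {path}") from exc
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise EncodingError(
            f"{path} is not valid UTF-8 at byte offset {exc.start}"
        ) from exc


def read_plaintext(path: str | Path, mode: str = "one-per-file") -> Corpus:
    """Read a plain-text corpus.

    ``mode="one-per-file"``: each file is one document (a directory yields one
    document per ``*.txt`` file, sorted by name). ``mode="one-per-line"``:
    each non-blank line of the file is one document with id ``<stem>:k`` for
    the k-th non-blank line; the physical line number is kept in ``source``.
    """
    path = Path(path)
    if mode == "one-per-file":
        if path.is_dir():
            files = sorted(p for p in path.iterdir() if p.suffix == ".txt")
            if not files:
                raise InputError(f"no .txt files in directory {path}")
            docs = [Document(p.stem, _read_utf8(p), str(p)) for p in files]
        else:
            docs = [Document(path.stem, _read_utf8(path), str(path))]
        return Corpus(tuple(docs))
    if mode == "one-per-line":
        text = _read_utf8(path)
        docs = []
        k = 0
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            k += 1
            docs.append(Document(f"{path.stem}:{k}", line, f"{path}#L{lineno}"))
        return Corpus(tuple(docs))
    raise ValueError(f"unknown mode {mode!r}; expected one-per-file or one-per-line")


def read_tabular(path: str | Path, id_col: str, text_col: str) -> Corpus:
    """Read a delimited table (CSV, or TSV for ``.tsv``) into a corpus.

    Rows with empty text are retained as empty documents. Duplicate ids are a
    hard error: silently suffixing them would corrupt provenance.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input path does not exist: {path}")
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                            encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise EncodingError(
            f"{path} is not valid UTF-8 at byte offset {exc.start}"
        ) from exc
    for col in (id_col, text_col):
        if col not in frame.columns:
            raise SchemaError(f"{path} has no column {col!r}")
    docs = [
        Document(str(row[id_col]), str(row[text_col]), f"{path}#row{i}")
        for i, row in frame.iterrows()
    ]
    return Corpus(tuple(docs))


_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def _parse_ris_records(text: str) -> list[dict[str, list[str]]]:
    records: list[dict[str, list[str]]] = []
    current: dict[str, list[str]] | None = None
    last_tag: str | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        m = _RIS_TAG.match(line)
        if m:
            tag, value = m.group(1), m.group(2).strip()
            if tag == "ER":
                if current is None:
                    raise RISParseError(
                        f"record terminator before any record (line {lineno})"
                    )
                records.append(current)
                current, last_tag = None, None
                continue
            if current is None:
                current = {}
            current.setdefault(tag, []).append(value)
            last_tag = tag
        else:
            # continuation line of the previous tag
            if current is None or last_tag is None:
                raise RISParseError(
                    f"unparseable line outside a record "
                    f"(record {len(records) + 1}, line {lineno})"
                )
            current[last_tag][-1] += " " + line.strip()
    if current is not None:
        raise RISParseError(
            f"record {len(records) + 1} is not terminated by 'ER  -'"
        )
    return records


def read_ris(path: str | Path) -> Corpus:
    """Read a RIS bibliographic export; one document per record with a
    non-empty abstract (``AB``) field. Ids come from the ``ID`` tag when
    present, else the record ordinal."""
    path = Path(path)
    records = _parse_ris_records(_read_utf8(path))
    docs = []
    for ordinal, record in enumerate(records, start=1):
        abstract = " ".join(v for v in record.get("AB", []) if v).strip()
        if not abstract:
            continue
        rid = next((v for v in record.get("ID", []) if v), str(ordinal))
        docs.append(Document(rid, abstract, f"{path}#record{ordinal}"))
    return Corpus(tuple(docs))


def links_to_frame(links: Iterable["CausalLink"]) -> pd.DataFrame:
    """Link records as a DataFrame with the canonical 8-column schema."""
    rows = [
        {
            "doc_id": l.doc_id,
            "sentence_index": l.sentence_index,
            "driver": l.driver,
            "keyword": l.keyword,
            "target": l.target,
            "weight": l.weight,
            "voice": l.voice,
            "sentence_text": l.sentence_text,
        }
        for l in links
    ]
    return pd.DataFrame(rows, columns=list(LINK_COLUMNS))


def write_links(links: Sequence["CausalLink"] | pd.DataFrame,
                path: str | Path) -> Path:
    """Write a link table as RFC-4180 CSV (embedded delimiters and newlines
    in the provenance sentence are quoted, so the table round-trips)."""
    frame = links if isinstance(links, pd.DataFrame) else links_to_frame(links)
    path = Path(path)
    try:
        frame.to_csv(path, index=False, encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
    return path


def read_links(path: str | Path) -> pd.DataFrame:
    """Read back a link table written by :func:`write_links`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"input path does not exist: {path}")
    frame = pd.read_csv(path, dtype={"doc_id": str, "driver": str,
                                     "keyword": str, "target": str,
                                     "voice": str, "sentence_text": str},
                        keep_default_na=False, encoding="utf-8")
    missing = [c for c in LINK_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path} lacks link columns: {missing}")
    if len(frame):
        frame["sentence_index"] = frame["sentence_index"].astype(int)
        frame["weight"] = frame["weight"].astype(float)
    return frame[list(LINK_COLUMNS)]
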