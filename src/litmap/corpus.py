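"""Bibliographic corpus I/O.

Two on-disk dialects are supported:

- the Web of Science tab-delimited headered export (two-letter field tags in
  the header row; ``;``-separated multi-value cells), read by
  :func:`read_wos_export`;
- a canonical internal TSV (columns ``record_id, title, abstract,
  author_keywords, keywords_plus, year`` with ``|``-joined lists), written by
  :func:`write_corpus` and read back by :func:`read_corpus`.

The canonical dialect round-trips: ``read_corpus(write_corpus(c)) == c``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from litmap.errors import CorpusFormatError

logger = logging.getLogger(__name__)

#: Header of the canonical TSV dialect.
CANONICAL_COLUMNS = ("record_id", "title", "abstract", "author_keywords", "keywords_plus", "year")

#: Separator used to join list-valued cells in the canonical TSV.
LIST_SEP = "|"


@dataclass
class ArticleRecord:
    """One bibliographic record, the unit searched by the tagger.

    Parameters
    ----------
    record_id
        Opaque unique identifier, e.g. a Web of Science "UT" accession.
    title
        Article title; must be non-empty.
    abstract
        Abstract text; may be empty (searched only when present).
    author_keywords
        Author-supplied keywords (WoS "DE" field).
    keywords_plus
        Index terms derived from cited titles (WoS "ID" field).
    year
        Publication year, if known.
    """

    record_id: str
    title: str
    abstract: str = ""
    author_keywords: list[str] = field(default_factory=list)
    keywords_plus: list[str] = field(default_factory=list)
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.record_id or not self.record_id.strip():
            raise ValueError("record_id must be non-empty")
        if not self.title or not self.title.strip():
            raise ValueError(f"record {self.record_id!r}: title must be non-empty")
        if self.year is not None and self.year < 1800:
            raise ValueError(f"record {self.record_id!r}: year {self.year} < 1800")
        # Empty/whitespace-only keyword entries are dropped at construction.
        self.author_keywords = [k for k in self.author_keywords if k.strip()]
        self.keywords_plus = [k for k in self.keywords_plus if k.strip()]


@dataclass
class Corpus:
    """An ordered collection of :class:`ArticleRecord` with distinct ids."""

    records: list[ArticleRecord] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise CorpusFormatError(f"duplicate record_id {rec.record_id!r} in corpus")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ArticleRecord]:
        return iter(self.records)


def _split_multivalue(cell: str) -> list[str]:
    """Split a ';'-separated WoS multi-value cell, trimming entries."""
    return [part.strip() for part in cell.split(";") if part.strip()]


def read_wos_export(path: str | Path, dialect: str = "tab_headered") -> Corpus:
    """Read a Web of Science tab-delimited headered export.

    The first row is a header of two-letter field tags; ``TI`` (title) and
    ``UT`` (accession id) are required, ``AB``/``DE``/``ID``/``PY`` optional.
    Unknown columns are tolerated and ignored.

    Raises
    ------
    CorpusFormatError
        Missing required column, duplicate ``UT``, empty ``UT``/``TI`` cell,
        or a row whose column count does not match the header.
    """
    if dialect != "tab_headered":
        raise ValueError(f"unsupported dialect {dialect!r}; only 'tab_headered' is implemented")
    path = Path(path)
    with open(path, encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        try:
            header = next(reader)
        except StopIteration:
            raise CorpusFormatError(f"{path}: empty file, no header row")
        header = [h.strip() for h in header]
        col = {tag: i for i, tag in enumerate(header)}
        for required in ("TI", "UT"):
            if required not in col:
                raise CorpusFormatError(f"{path}: missing required column tag {required!r}")
        for optional in ("AB", "DE", "ID"):
            if optional not in col:
                logger.warning("%s: column %r absent; affected fields will be empty", path, optional)

        records: list[ArticleRecord] = []
        seen: set[str] = set()
        for rownum, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # trailing blank line
            if len(row) != len(header):
                raise CorpusFormatError(
                    f"{path}: row {rownum} has {len(row)} columns, expected {len(header)}"
                )
            ut = row[col["UT"]].strip()
            ti = row[col["TI"]].strip()
            if not ut:
                raise CorpusFormatError(f"{path}: row {rownum} has an empty UT cell")
            if not ti:
                raise CorpusFormatError(f"{path}: row {rownum} (UT {ut!r}) has an empty TI cell")
            if ut in seen:
                raise CorpusFormatError(f"{path}: duplicate UT {ut!r} at row {rownum}")
            seen.add(ut)

            def cell(tag: str) -> str:
                return row[col[tag]].strip() if tag in col else ""

            year: Optional[int] = None
            py = cell("PY")
            if py:
                try:
                    year = int(py)
                except ValueError:
                    raise CorpusFormatError(f"{path}: row {rownum}: non-integer PY cell {py!r}")
            records.append(
                ArticleRecord(
                    record_id=ut,
                    title=ti,
                    abstract=cell("AB"),
                    author_keywords=_split_multivalue(cell("DE")),
                    keywords_plus=_split_multivalue(cell("ID")),
                    year=year,
                )
            )
    return Corpus(records=records, source_label=str(path))


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus to the canonical TSV dialect.

    List-valued fields are ``|``-joined, so individual keywords must not
    contain the separator; tabs/newlines in free text are quoted by the CSV
    layer and round-trip cleanly.
    """
    path = Path(path)
    for rec in corpus:
        for kw in list(rec.author_keywords) + list(rec.keywords_plus):
            if LIST_SEP in kw:
                raise ValueError(
                    f"record {rec.record_id!r}: keyword {kw!r} contains the list separator {LIST_SEP!r}"
                )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for rec in corpus:
            writer.writerow(
                [
                    rec.record_id,
                    rec.title,
                    rec.abstract,
                    LIST_SEP.join(rec.author_keywords),
                    LIST_SEP.join(rec.keywords_plus),
                    "" if rec.year is None else str(rec.year),
                ]
            )


def read_corpus(path: str | Path) -> Corpus:
    """Read a corpus previously written by :func:`write_corpus`."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_MINIMAL)
        try:
            header = next(reader)
        except StopIteration:
            raise CorpusFormatError(f"{path}: empty file, no header row")
        if tuple(header) != CANONICAL_COLUMNS:
            raise CorpusFormatError(
                f"{path}: unexpected header {header!r}; expected {list(CANONICAL_COLUMNS)}"
            )
        records = []
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CANONICAL_COLUMNS):
                raise CorpusFormatError(
                    f"{path}: row {rownum} has {len(row)} columns, expected {len(CANONICAL_COLUMNS)}"
                )
            record_id, title, abstract, de, idk, py = row
            records.append(
                ArticleRecord(
                    record_id=record_id,
                    title=title,
                    abstract=abstract,
                    author_keywords=de.split(LIST_SEP) if de else [],
                    keywords_plus=idk.split(LIST_SEP) if idk else [],
                    year=int(py) if py else None,
                )
            )
    return Corpus(records=records, source_label=str(path))


def collect_keywords_plus(corpus: Corpus) -> list[str]:
    """Collect the deduplicated, sorted list of KeyWords Plus across a corpus.

    Keywords are normalized (lowercased, hyphens folded, whitespace collapsed)
    before deduplication, and the normalized forms are returned sorted
    lexicographically. This is the raw material for keyword-to-node
    assignment curation.
    """
    from litmap.tagger import normalize_text

    seen: set[str] = set()
    for rec in corpus:
        for kw in rec.keywords_plus:
            norm = normalize_text(kw)
            if norm:
                seen.add(norm)
    return sorted(seen)
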