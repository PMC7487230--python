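"""Concept tagging: search each article's text for assigned keywords.

An article's searchable document is the normalized, space-joined
concatenation of its title, abstract, author keywords and KeyWords Plus.
Every keyword assignment whose phrase occurs in the document contributes its
parent node (and child node, if any) to the article's tag sets. Tagging is
binary per concept: match multiplicity is recorded as evidence but never
weights counts.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

if TYPE_CHECKING:  # pragma: no cover
    from litmap.corpus import ArticleRecord, Corpus
    from litmap.scheme import ConceptScheme

logger = logging.getLogger(__name__)

_DASHES = "‐‑‒–—−-"  # hyphens, en/em dashes, minus
_DASH_RE = re.compile("[%s]" % _DASHES)
_WS_RE = re.compile(r"\s+")


class BoundaryMode(str, enum.Enum):
    """How a keyword phrase must align with word boundaries in the document.

    ``substring``
        Plain substring containment anywhere.
    ``word_start``
        The occurrence must begin at a word boundary but may end mid-word, so
        "life history" matches "life history traits" and "pollinat" matches
        "pollinators", while "rarity" does not match inside "temporarity".
    ``word``
        Boundaries required at both ends of the occurrence.
    """

    SUBSTRING = "substring"
    WORD_START = "word_start"
    WORD = "word"


@dataclass(frozen=True)
class TagOptions:
    """Matching semantics knobs; the defaults are the documented behavior."""

    case_fold: bool = True
    hyphen_fold: bool = True
    boundary_mode: BoundaryMode = BoundaryMode.WORD_START

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundary_mode", BoundaryMode(self.boundary_mode))


DEFAULT_OPTIONS = TagOptions()


@dataclass
class TaggedArticle:
    """The concepts detected in one record, with per-keyword evidence.

    ``matches`` holds ``(keyword, node_names)`` pairs, one per matched
    assignment; every tag in ``parent_tags``/``child_tags`` is justified by at
    least one evidence entry, and every child tag's parent is present.
    """

    record_id: str
    parent_tags: set[str] = field(default_factory=set)
    child_tags: set[str] = field(default_factory=set)
    matches: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)


@dataclass
class TagSummary:
    """Corpus-level tagging totals."""

    n_articles: int
    articles_per_concept: dict[str, int]
    untagged_count: int


def normalize_text(text: str, options: TagOptions = DEFAULT_OPTIONS) -> str:
    """Canonicalize text for matching.

    Lowercases (if ``case_fold``), folds hyphens/en-dashes to spaces (if
    ``hyphen_fold``), collapses whitespace runs to single spaces, and strips.
    Idempotent.
    """
    if options.case_fold:
        text = text.lower()
    if options.hyphen_fold:
        text = _DASH_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def _compile_keyword(keyword: str, options: TagOptions) -> re.Pattern[str]:
    pattern = re.escape(keyword)
    if options.boundary_mode in (BoundaryMode.WORD_START, BoundaryMode.WORD):
        pattern = r"(?<!\w)" + pattern
    if options.boundary_mode is BoundaryMode.WORD:
        pattern = pattern + r"(?!\w)"
    return re.compile(pattern)


def match_keyword(keyword: str, document: str, options: TagOptions = DEFAULT_OPTIONS) -> bool:
    """True iff a (pre-normalized) keyword phrase occurs in a document.

    Both arguments are expected to be already normalized with the same
    options; an empty keyword is unmatchable and raises ``ValueError``.
    """
    if not keyword:
        raise ValueError("empty keyword is unmatchable")
    if options.boundary_mode is BoundaryMode.SUBSTRING:
        return keyword in document
    return _compile_keyword(keyword, options).search(document) is not None


def searchable_document(record: "ArticleRecord", options: TagOptions = DEFAULT_OPTIONS) -> str:
    """The normalized concatenation of all searched fields of a record."""
    parts = [record.title, record.abstract, *record.author_keywords, *record.keywords_plus]
    return normalize_text(" ".join(p for p in parts if p), options)


def tag_article(
    record: "ArticleRecord",
    scheme: "ConceptScheme",
    options: TagOptions = DEFAULT_OPTIONS,
) -> TaggedArticle:
    """Tag one record with every concept whose keywords occur in its text."""
    return _tag_one(record, _prepare_assignments(scheme, options), options)


def tag_corpus(
    corpus: "Corpus",
    scheme: "ConceptScheme",
    options: TagOptions = DEFAULT_OPTIONS,
) -> tuple[list[TaggedArticle], TagSummary]:
    """Tag every record in a corpus; order preserved.

    Returns the tagged articles and a summary: articles per concept (parents
    and children) and the number of untagged articles.
    """
    prepared = _prepare_assignments(scheme, options)
    tagged = [_tag_one(rec, prepared, options) for rec in corpus]

    per_concept: dict[str, int] = {node.name: 0 for node in scheme.nodes}
    untagged = 0
    for ta in tagged:
        if not ta.parent_tags:
            untagged += 1
        for name in ta.parent_tags | ta.child_tags:
            per_concept[name] = per_concept.get(name, 0) + 1
    return tagged, TagSummary(
        n_articles=len(tagged),
        articles_per_concept=per_concept,
        untagged_count=untagged,
    )


def _prepare_assignments(
    scheme: "ConceptScheme", options: TagOptions
) -> list[tuple[str, Optional[re.Pattern[str]], str, Optional[str]]]:
    """Pre-normalize and pre-compile every assignment's keyword once."""
    prepared = []
    for a in scheme.assignments:
        kw = normalize_text(a.keyword, options)
        if not kw:
            logger.warning("assignment with empty normalized keyword skipped: %r", a.keyword)
            continue
        pat = None
        if options.boundary_mode is not BoundaryMode.SUBSTRING:
            pat = _compile_keyword(kw, options)
        prepared.append((kw, pat, a.parent_name, a.child_name))
    return prepared


def _tag_one(record, prepared, options: TagOptions) -> TaggedArticle:
    doc = searchable_document(record, options)
    out = TaggedArticle(record_id=record.record_id)
    for kw, pat, parent, child in prepared:
        hit = (kw in doc) if pat is None else (pat.search(doc) is not None)
        if not hit:
            continue
        nodes = (parent,) if child is None else (parent, child)
        out.matches.append((kw, nodes))
        out.parent_tags.add(parent)
        if child is not None:
            out.child_tags.add(child)
    return out


# --- tags TSV round trip (CLI artifact format) -------------------------------

_TAGS_COLUMNS = ("record_id", "parent_tags", "child_tags", "evidence")


def write_tags(tagged: Iterable[TaggedArticle], path) -> None:
    """Write tags to TSV: record_id, '|'-joined parent/child tags, evidence.

    Evidence entries have the form ``keyword=>Parent[/Child]``.
    """
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TAGS_COLUMNS)
        for ta in tagged:
            evidence = "|".join(f"{kw}=>{'/'.join(nodes)}" for kw, nodes in ta.matches)
            writer.writerow(
                [
                    ta.record_id,
                    "|".join(sorted(ta.parent_tags)),
                    "|".join(sorted(ta.child_tags)),
                    evidence,
                ]
            )


def read_tags(path) -> list[TaggedArticle]:
    """Read a tags TSV written by :func:`write_tags`."""
    import csv

    from litmap.errors import CorpusFormatError

    out: list[TaggedArticle] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != _TAGS_COLUMNS:
            raise CorpusFormatError(f"{path}: unexpected tags header {header!r}")
        for row in reader:
            if not row:
                continue
            record_id, parents, children, evidence = row
            matches = []
            if evidence:
                for entry in evidence.split("|"):
                    kw, _, nodes = entry.partition("=>")
                    matches.append((kw, tuple(nodes.split("/"))))
            out.append(
                TaggedArticle(
                    record_id=record_id,
                    parent_tags=set(parents.split("|")) if parents else set(),
                    child_tags=set(children.split("|")) if children else set(),
                    matches=matches,
                )
            )
    return out
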