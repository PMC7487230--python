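"""Hierarchical concept scheme and keyword-to-node assignment map.

The scheme is two-level: parent nodes grouped into open-ended categories
(e.g. "Ecology", "Evolution", "General Characteristics"), with optional
finer-scale child nodes under each parent. Each curated keyword is assigned
to exactly one parent and at most one child of that parent; a child's
keywords also count toward its parent. A default node table with 14 parents
in three categories ships with the package (``litmap/data/default_nodes.csv``).

Keywords are stored normalized (see :func:`litmap.tagger.normalize_text`) so
the map and the matcher agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from litmap.errors import SchemeValidationError
from litmap.tagger import normalize_text

logger = logging.getLogger(__name__)

PARENT = "parent"
CHILD = "child"


@dataclass(frozen=True)
class ConceptNode:
    """A parent- or child-level concept node."""

    name: str
    category: str
    level: str  # PARENT or CHILD
    parent_name: Optional[str] = None  # required iff level == CHILD

    def __post_init__(self) -> None:
        if self.level not in (PARENT, CHILD):
            raise ValueError(f"node {self.name!r}: level must be 'parent' or 'child', got {self.level!r}")
        if self.level == CHILD and not self.parent_name:
            raise ValueError(f"child node {self.name!r} requires parent_name")
        if self.level == PARENT and self.parent_name:
            raise ValueError(f"parent node {self.name!r} must not set parent_name")


@dataclass(frozen=True)
class KeywordAssignment:
    """One curated keyword mapped to a parent node (and optionally a child)."""

    keyword: str
    parent_name: str
    child_name: Optional[str] = None


class ConceptScheme:
    """A validated concept scheme: nodes plus keyword assignments.

    Construction normalizes keywords and raises
    :class:`~litmap.errors.SchemeValidationError` listing *every* violation if
    the scheme is inconsistent (pass ``validate=False`` to build anyway, e.g.
    to inspect violations with :func:`validate_scheme`).
    """

    def __init__(
        self,
        nodes: Iterable[ConceptNode],
        assignments: Iterable[KeywordAssignment] = (),
        validate: bool = True,
    ) -> None:
        self.nodes: list[ConceptNode] = list(nodes)
        self.assignments: list[KeywordAssignment] = [
            KeywordAssignment(normalize_text(a.keyword), a.parent_name, a.child_name)
            for a in assignments
        ]
        self._by_name: dict[str, ConceptNode] = {}
        for node in self.nodes:
            self._by_name.setdefault(node.name, node)
        if validate:
            violations = validate_scheme(self)
            if violations:
                raise SchemeValidationError(violations)
            for node in self.nodes if self.assignments else ():
                if self.keyword_count(node.name) == 0:
                    logger.warning(
                        "node %r has zero assigned keywords; it will be omitted from networks",
                        node.name,
                    )

    # -- lookups --------------------------------------------------------------

    def node(self, name: str) -> ConceptNode:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def parents(self) -> list[ConceptNode]:
        return [n for n in self.nodes if n.level == PARENT]

    def children(self) -> list[ConceptNode]:
        return [n for n in self.nodes if n.level == CHILD]

    def children_of(self, parent_name: str) -> list[ConceptNode]:
        return [n for n in self.nodes if n.level == CHILD and n.parent_name == parent_name]

    def categories(self) -> list[str]:
        seen: list[str] = []
        for n in self.nodes:
            if n.category not in seen:
                seen.append(n.category)
        return seen

    def keyword_count(self, name: str) -> int:
        """Number of assignments naming this node.

        For a parent this counts every assignment with that parent (a child's
        keywords also count toward its parent); for a child, only assignments
        that name the child. This count is the normalization ingredient of the
        connectivity statistic.
        """
        node = self._by_name[name]
        if node.level == PARENT:
            return sum(1 for a in self.assignments if a.parent_name == name)
        return sum(1 for a in self.assignments if a.child_name == name)

    def assigned_keywords(self) -> set[str]:
        return {a.keyword for a in self.assignments}


def validate_scheme(scheme: ConceptScheme) -> list[str]:
    """Return a description of every invariant violation (empty list if valid)."""
    violations: list[str] = []

    seen: set[str] = set()
    for node in scheme.nodes:
        if node.name in seen:
            violations.append(f"duplicate node name {node.name!r}")
        seen.add(node.name)

    by_name = {n.name: n for n in scheme.nodes}
    for node in scheme.nodes:
        if node.level == CHILD:
            parent = by_name.get(node.parent_name)
            if parent is None:
                violations.append(
                    f"child node {node.name!r} references nonexistent parent {node.parent_name!r}"
                )
            elif parent.level != PARENT:
                violations.append(
                    f"child node {node.name!r} references non-parent node {node.parent_name!r}"
                )

    seen_kw: set[str] = set()
    for a in scheme.assignments:
        if a.keyword in seen_kw:
            violations.append(f"keyword {a.keyword!r} has multiple assignments")
        seen_kw.add(a.keyword)
        parent = by_name.get(a.parent_name)
        if parent is None or parent.level != PARENT:
            violations.append(
                f"keyword {a.keyword!r} assigned to unknown or non-parent node {a.parent_name!r}"
            )
        if a.child_name is not None:
            child = by_name.get(a.child_name)
            if child is None or child.level != CHILD:
                violations.append(
                    f"keyword {a.keyword!r} assigned to unknown or non-child node {a.child_name!r}"
                )
            elif child.parent_name != a.parent_name:
                violations.append(
                    f"keyword {a.keyword!r}: child {a.child_name!r} is not a child of {a.parent_name!r}"
                )
    return violations


def unassigned_keywords(keywords: Iterable[str], scheme: ConceptScheme) -> list[str]:
    """Normalized input keywords lacking any assignment, input order preserved."""
    assigned = scheme.assigned_keywords()
    out = []
    for kw in keywords:
        norm = normalize_text(kw)
        if norm not in assigned:
            out.append(norm)
    return out


# -- file formats -------------------------------------------------------------


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")


def read_nodes_csv(path: str | Path) -> list[ConceptNode]:
    """Read a nodes CSV (columns ``category,parent,child``; one row per node).

    A row with an empty ``child`` cell declares a parent node; a row with a
    non-empty ``child`` declares a child node under ``parent``.
    """
    df = _read_csv(path)
    for column in ("category", "parent", "child"):
        if column not in df.columns:
            raise SchemeValidationError([f"{path}: nodes file missing column {column!r}"])
    nodes: list[ConceptNode] = []
    for _, row in df.iterrows():
        category = row["category"].strip()
        parent = row["parent"].strip()
        child = row["child"].strip()
        if not parent:
            raise SchemeValidationError([f"{path}: node row with empty parent cell"])
        if child:
            nodes.append(ConceptNode(name=child, category=category, level=CHILD, parent_name=parent))
        else:
            nodes.append(ConceptNode(name=parent, category=category, level=PARENT))
    return nodes


def read_keyword_map_csv(path: str | Path) -> list[KeywordAssignment]:
    """Read a keyword map CSV (columns ``keyword,parent,child``; child optional)."""
    df = _read_csv(path)
    for column in ("keyword", "parent"):
        if column not in df.columns:
            raise SchemeValidationError([f"{path}: keyword map missing column {column!r}"])
    has_child = "child" in df.columns
    assignments: list[KeywordAssignment] = []
    for _, row in df.iterrows():
        child = row["child"].strip() if has_child else ""
        assignments.append(
            KeywordAssignment(
                keyword=row["keyword"].strip(),
                parent_name=row["parent"].strip(),
                child_name=child or None,
            )
        )
    return assignments


def load_scheme(nodes_file: str | Path, keyword_map_file: str | Path) -> ConceptScheme:
    """Load and validate a concept scheme from its two CSV files."""
    return ConceptScheme(read_nodes_csv(nodes_file), read_keyword_map_csv(keyword_map_file))


def write_nodes_csv(nodes: Iterable[ConceptNode], path: str | Path) -> None:
    rows = []
    for n in nodes:
        if n.level == PARENT:
            rows.append({"category": n.category, "parent": n.name, "child": ""})
        else:
            rows.append({"category": n.category, "parent": n.parent_name, "child": n.name})
    pd.DataFrame(rows, columns=["category", "parent", "child"]).to_csv(path, index=False)


def write_keyword_map_csv(assignments: Iterable[KeywordAssignment], path: str | Path) -> None:
    rows = [
        {"keyword": a.keyword, "parent": a.parent_name, "child": a.child_name or ""}
        for a in assignments
    ]
    pd.DataFrame(rows, columns=["keyword", "parent", "child"]).to_csv(path, index=False)


def default_nodes_path() -> Path:
    """Path of the packaged default node table (14 parents, 3 categories)."""
    return Path(str(resources.files("litmap").joinpath("data/default_nodes.csv")))


def load_default_nodes() -> list[ConceptNode]:
    """The packaged default node table as a list of nodes (no assignments)."""
    return read_nodes_csv(default_nodes_path())
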