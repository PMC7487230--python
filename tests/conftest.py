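"""Shared fixtures and small factories for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from litmap.corpus import ArticleRecord, Corpus
from litmap.scheme import CHILD, PARENT, ConceptNode, ConceptScheme, KeywordAssignment
from litmap.simulate import ConceptSpec, SyntheticConfig
from litmap.tagger import TaggedArticle


def make_scheme(parent_keywords: dict[str, list[str]], categories: dict[str, str] | None = None,
                children: dict[str, dict[str, list[str]]] | None = None) -> ConceptScheme:
    """Build a scheme from {parent: [keywords]} plus optional
    {parent: {child: [keywords]}}; child keywords also count toward the parent.
    """
    categories = categories or {}
    children = children or {}
    nodes: list[ConceptNode] = []
    assignments: list[KeywordAssignment] = []
    for parent, kws in parent_keywords.items():
        nodes.append(ConceptNode(parent, categories.get(parent, "General"), PARENT))
        assignments.extend(KeywordAssignment(kw, parent) for kw in kws)
    for parent, kids in children.items():
        for child, kws in kids.items():
            nodes.append(ConceptNode(child, categories.get(parent, "General"), CHILD, parent))
            assignments.extend(KeywordAssignment(kw, parent, child) for kw in kws)
    return ConceptScheme(nodes, assignments)


def make_tags(*tagsets: set[str], children: dict[int, set[str]] | None = None) -> list[TaggedArticle]:
    """TaggedArticles from parent tag sets (evidence filled in mechanically)."""
    children = children or {}
    out = []
    for i, parents in enumerate(tagsets):
        child_tags = children.get(i, set())
        matches = [(f"kw{j}", (t,)) for j, t in enumerate(sorted(parents | child_tags))]
        out.append(TaggedArticle(f"R{i:04d}", set(parents), set(child_tags), matches))
    return out


@pytest.fixture
def two_parent_scheme() -> ConceptScheme:
    return make_scheme(
        {"Microevolution": ["gene flow", "genetic drift"], "Physiology": ["photosynthesis"]},
        children={"Microevolution": {"Gene Flow": ["dispersal corridors"]}},
    )


@pytest.fixture
def eight_concept_config() -> SyntheticConfig:
    names = [f"Concept{i}" for i in range(8)]
    return SyntheticConfig(
        n_articles=200,
        concepts=[ConceptSpec(n, "Ecology" if i < 4 else "Evolution", 3 + i % 3)
                  for i, n in enumerate(names)],
        base_prevalence={n: 0.15 + 0.05 * (i % 4) for i, n in enumerate(names)},
        pair_boost={frozenset(("Concept0", "Concept5")): 2.5},
        keyword_emission_prob=1.0,
        seed=2024,
    )


def random_corpus(rng: np.random.Generator, n: int = 20) -> Corpus:
    """A corpus of records with varied unicode-ish free text for round trips."""
    words = ["habitat", "Rarity", "life‐history", "élan", "drift", "N=5", 'say "so"']
    records = []
    for i in range(n):
        records.append(
            ArticleRecord(
                record_id=f"WOS:{i:09d}",
                title=" ".join(rng.choice(words, size=rng.integers(1, 6))),
                abstract="" if rng.random() < 0.3 else " ".join(rng.choice(words, size=10)),
                author_keywords=[str(w) for w in rng.choice(words, size=rng.integers(0, 4))],
                keywords_plus=[str(w) for w in rng.choice(words, size=rng.integers(0, 4))],
                year=None if rng.random() < 0.2 else int(rng.integers(1900, 2026)),
            )
        )
    return Corpus(records=records, source_label="random")
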