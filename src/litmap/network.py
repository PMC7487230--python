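"""Co-occurrence counting and the keyword-normalized connectivity network.

The co-occurrence matrix holds, for a fixed node list, per-concept article
counts on the diagonal and pairwise both-tagged counts off the diagonal.
The connectivity of a pair {a, b} is

    C_ab = N_ab / (K_a + K_b)

where N_ab is the number of articles tagged with both concepts and K_a, K_b
are the numbers of keywords assigned to each concept. Edges exist only where
N_ab > 0; a node's weighted degree is the sum of its incident connectivity
values. The median connectivity over existing edges splits the network into
relatively strong connections and a strictly-below-median "weak" sub-network;
the parents involved in the top-k strongest pairs seed a child-level
drill-down network.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from litmap.scheme import CHILD, PARENT, ConceptScheme
from litmap.tagger import TaggedArticle

logger = logging.getLogger(__name__)


@dataclass
class CooccurrenceMatrix:
    """Symmetric pairwise study counts with per-concept counts on the diagonal."""

    node_names: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.node_names)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts matrix must be symmetric")
        diag = np.diag(self.counts)
        bound = np.minimum.outer(diag, diag)
        off = ~np.eye(n, dtype=bool)
        if np.any(self.counts[off] > bound[off]):
            raise ValueError("pair count exceeds min of the two concept counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.node_names, columns=self.node_names)


@dataclass(frozen=True)
class NetworkNode:
    name: str
    category: str
    keyword_count: int
    weighted_degree: float


@dataclass(frozen=True)
class NetworkEdge:
    """An undirected edge; ``source < target`` lexicographically."""

    source: str
    target: str
    study_count: int
    connectivity: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass
class ConnectivityNetwork:
    nodes: list[NetworkNode] = field(default_factory=list)
    edges: list[NetworkEdge] = field(default_factory=list)
    median_connectivity: Optional[float] = None

    def node(self, name: str) -> NetworkNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]


def cooccurrence_counts(
    tags: Iterable[TaggedArticle],
    node_names: Sequence[str],
    level: str = PARENT,
    scheme: Optional[ConceptScheme] = None,
) -> CooccurrenceMatrix:
    """Count per-concept and pairwise-tagged articles over ``node_names``.

    One increment per article per unordered tagged pair; the diagonal holds
    per-concept article counts. Tags outside ``node_names`` are ignored. If a
    ``scheme`` is supplied, every requested name must be a scheme node at the
    requested ``level``.
    """
    if level not in (PARENT, CHILD):
        raise ValueError(f"level must be 'parent' or 'child', got {level!r}")
    if scheme is not None:
        for name in node_names:
            if name not in scheme:
                raise KeyError(f"unknown node name {name!r}")
            if scheme.node(name).level != level:
                raise KeyError(f"node {name!r} is not at level {level!r}")
    if len(set(node_names)) != len(node_names):
        raise ValueError("node_names contains duplicates")

    index = {name: i for i, name in enumerate(node_names)}
    n = len(node_names)
    counts = np.zeros((n, n), dtype=np.int64)
    for ta in tags:
        tagset = ta.parent_tags if level == PARENT else ta.child_tags
        idx = sorted(index[t] for t in tagset if t in index)
        for pos, i in enumerate(idx):
            counts[i, i] += 1
            for j in idx[pos + 1 :]:
                counts[i, j] += 1
                counts[j, i] += 1
    return CooccurrenceMatrix(node_names=list(node_names), counts=counts)


def connectivity_network(counts: CooccurrenceMatrix, scheme: ConceptScheme) -> ConnectivityNetwork:
    """Build the connectivity network from a co-occurrence matrix.

    Nodes with zero assigned keywords are excluded (with a warning) before any
    computation; remaining nodes are kept even if isolated. Edges exist for
    every pair with N_ab > 0, weighted C_ab = N_ab / (K_a + K_b).
    """
    kept: list[str] = []
    for name in counts.node_names:
        if name not in scheme:
            raise KeyError(f"unknown node name {name!r}")
        if scheme.keyword_count(name) == 0:
            logger.warning("node %r has zero keywords; omitted from the network", name)
        else:
            kept.append(name)

    K = {name: scheme.keyword_count(name) for name in kept}
    index = {name: i for i, name in enumerate(counts.node_names)}
    edges: list[NetworkEdge] = []
    degree: dict[str, float] = {name: 0.0 for name in kept}
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            n_ab = int(counts.counts[index[a], index[b]])
            if n_ab == 0:
                continue
            src, dst = sorted((a, b))
            c = n_ab / (K[a] + K[b])
            edges.append(NetworkEdge(source=src, target=dst, study_count=n_ab, connectivity=c))
            degree[a] += c
            degree[b] += c
    edges.sort(key=lambda e: e.pair)

    nodes = [
        NetworkNode(
            name=name,
            category=scheme.node(name).category,
            keyword_count=K[name],
            weighted_degree=degree[name],
        )
        for name in kept
    ]
    median = statistics.median(e.connectivity for e in edges) if edges else None
    return ConnectivityNetwork(nodes=nodes, edges=edges, median_connectivity=median)


def median_connectivity(network: ConnectivityNetwork) -> float:
    """Standard median over edge connectivity values (midpoint for even counts)."""
    if not network.edges:
        raise ValueError("median undefined: network has no edges")
    return statistics.median(e.connectivity for e in network.edges)


def below_median_subnetwork(network: ConnectivityNetwork) -> ConnectivityNetwork:
    """The sub-network of edges strictly below the median connectivity.

    Retains only nodes incident to a retained edge; weighted degrees (and the
    sub-network's own median) are recomputed within the sub-network.
    """
    median = median_connectivity(network)
    edges = [e for e in network.edges if e.connectivity < median]
    incident = {name for e in edges for name in e.pair}
    degree = {name: 0.0 for name in incident}
    for e in edges:
        degree[e.source] += e.connectivity
        degree[e.target] += e.connectivity
    nodes = [
        NetworkNode(n.name, n.category, n.keyword_count, degree[n.name])
        for n in network.nodes
        if n.name in incident
    ]
    sub_median = statistics.median(e.connectivity for e in edges) if edges else None
    return ConnectivityNetwork(nodes=nodes, edges=edges, median_connectivity=sub_median)


def top_k_pairs(network: ConnectivityNetwork, k: int) -> list[NetworkEdge]:
    """The k strongest edges, sorted by connectivity descending.

    Ties break by lexicographic order of the sorted pair names.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if len(network.edges) < k:
        raise ValueError(f"requested top {k} edges but only {len(network.edges)} exist")
    ranked = sorted(network.edges, key=lambda e: (-e.connectivity, e.pair))
    return ranked[:k]


def child_network(
    tags: Iterable[TaggedArticle],
    scheme: ConceptScheme,
    parent_subset: set[str],
) -> ConnectivityNetwork:
    """Drill-down network over the child nodes of a set of parents.

    The node set is every child of a parent in ``parent_subset`` with at least
    one assigned keyword; counts come from child-level tags, connectivity is
    normalized by child keyword counts. Childless parents contribute nothing.
    """
    if not parent_subset:
        raise ValueError("parent_subset must be non-empty")
    for name in parent_subset:
        if name not in scheme or scheme.node(name).level != PARENT:
            raise KeyError(f"unknown parent node {name!r}")
    child_names = [
        c.name
        for p in sorted(parent_subset)
        for c in scheme.children_of(p)
        if scheme.keyword_count(c.name) > 0
    ]
    if not child_names:
        logger.warning("no eligible child nodes under parents %s", sorted(parent_subset))
        return ConnectivityNetwork(nodes=[], edges=[], median_connectivity=None)
    counts = cooccurrence_counts(tags, child_names, level=CHILD, scheme=scheme)
    return connectivity_network(counts, scheme)


# -- serialization ------------------------------------------------------------


def network_to_dict(network: ConnectivityNetwork) -> dict:
    return {
        "nodes": [
            {
                "name": n.name,
                "category": n.category,
                "keyword_count": n.keyword_count,
                "weighted_degree": n.weighted_degree,
            }
            for n in network.nodes
        ],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "study_count": e.study_count,
                "connectivity": e.connectivity,
            }
            for e in network.edges
        ],
        "median_connectivity": network.median_connectivity,
    }


def network_from_dict(data: dict) -> ConnectivityNetwork:
    return ConnectivityNetwork(
        nodes=[NetworkNode(**n) for n in data["nodes"]],
        edges=[NetworkEdge(**e) for e in data["edges"]],
        median_connectivity=data.get("median_connectivity"),
    )


def write_matrix_csv(counts: CooccurrenceMatrix, path) -> None:
    """Square count matrix CSV with node names on both axes."""
    counts.to_frame().to_csv(path, index_label="")


def read_matrix_csv(path) -> CooccurrenceMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: matrix row and column labels differ")
    return CooccurrenceMatrix(node_names=list(df.columns), counts=df.to_numpy())


def connectivity_matrix_frame(network: ConnectivityNetwork) -> pd.DataFrame:
    """Square connectivity-value matrix (zero diagonal, zeros for absent edges)."""
    names = network.node_names()
    df = pd.DataFrame(0.0, index=names, columns=names)
    for e in network.edges:
        df.loc[e.source, e.target] = e.connectivity
        df.loc[e.target, e.source] = e.connectivity
    return df
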