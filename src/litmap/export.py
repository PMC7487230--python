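"""Deterministic circular layout, visual scaling, and GEXF/GraphML export.

Nodes are placed on a unit circle, ordered by (category rank, alphabetical
name) and walked counter-clockwise from 90 degrees. Label sizes scale
affinely with weighted degree, edge thickness with connectivity. Files are
written with a fixed attribute order and deterministic shortest round-trip
number formatting, so identical inputs yield byte-identical output; both formats
re-parse (e.g. with networkx or Gephi) to the same node/edge attributes.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from litmap.network import ConnectivityNetwork

GEXF_NS = "http://www.gexf.net/1.2draft"
GEXF_VIZ_NS = "http://www.gexf.net/1.2draft/viz"
GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


@dataclass
class LayoutPosition:
    """Unit-circle coordinates per node plus the angular ordering."""

    positions: dict[str, tuple[float, float]]
    order: list[str]


@dataclass
class VisualAttributes:
    """Affinely scaled label sizes (per node) and edge thicknesses (per edge)."""

    label_size: dict[str, float] = field(default_factory=dict)
    edge_thickness: dict[tuple[str, str], float] = field(default_factory=dict)


def circular_layout(
    network: ConnectivityNetwork,
    category_order: Sequence[str],
    start_angle_deg: float = 90.0,
    clockwise: bool = False,
) -> LayoutPosition:
    """Place nodes on a unit circle, categories contiguous, names alphabetical.

    Nodes are sorted by (rank of category in ``category_order``, name) and
    placed at equal angular gaps of 360/n degrees, counter-clockwise from
    ``start_angle_deg`` by default. Deterministic. Unknown categories are
    fatal.
    """
    rank = {cat: i for i, cat in enumerate(category_order)}
    for node in network.nodes:
        if node.category not in rank:
            raise KeyError(
                f"node {node.name!r} has category {node.category!r} not in category_order"
            )
    ordered = sorted(network.nodes, key=lambda n: (rank[n.category], n.name))
    n = len(ordered)
    positions: dict[str, tuple[float, float]] = {}
    direction = -1.0 if clockwise else 1.0
    for i, node in enumerate(ordered):
        theta = math.radians(start_angle_deg) + direction * 2.0 * math.pi * i / max(n, 1)
        positions[node.name] = (math.cos(theta), math.sin(theta))
    return LayoutPosition(positions=positions, order=[n_.name for n_ in ordered])


def _affine(values: dict, lo: float, hi: float) -> dict:
    if not values:
        return {}
    vmin = min(values.values())
    vmax = max(values.values())
    if vmax == vmin:
        mid = (lo + hi) / 2.0
        return {k: mid for k in values}
    scale = (hi - lo) / (vmax - vmin)
    return {k: lo + (v - vmin) * scale for k, v in values.items()}


def scale_visuals(
    network: ConnectivityNetwork,
    size_range: tuple[float, float] = (8.0, 40.0),
    width_range: tuple[float, float] = (0.5, 8.0),
) -> VisualAttributes:
    """Min-max scale weighted degrees into label sizes, connectivities into widths.

    Degenerate inputs (all values equal) map to the range midpoint; an empty
    network yields empty attributes.
    """
    for lo, hi in (size_range, width_range):
        if lo <= 0 or hi <= 0 or lo >= hi:
            raise ValueError(f"range ({lo}, {hi}) must be positive with min < max")
    sizes = _affine({n.name: n.weighted_degree for n in network.nodes}, *size_range)
    widths = _affine({e.pair: e.connectivity for e in network.edges}, *width_range)
    return VisualAttributes(label_size=sizes, edge_thickness=widths)


def _fmt(x: float) -> str:
    """Deterministic shortest round-trip float formatting.

    Chosen over fixed significant digits so that re-parsing reproduces every
    numeric attribute exactly while output stays byte-stable.
    """
    return repr(float(x))


def write_graph(
    network: ConnectivityNetwork,
    layout: LayoutPosition,
    visuals: VisualAttributes,
    path: str | Path,
    format: str = "gexf",
) -> None:
    """Write the network as an undirected GEXF 1.2draft or GraphML file.

    Node attributes: category, keyword_count, weighted_degree, x, y,
    label_size. Edge attributes: study_count, connectivity (also the edge
    weight), thickness. Byte-identical for identical inputs.
    """
    for node in network.nodes:
        if node.name not in layout.positions:
            raise ValueError(f"layout missing node {node.name!r}")
        if node.name not in visuals.label_size:
            raise ValueError(f"visuals missing label size for node {node.name!r}")
    for edge in network.edges:
        if edge.pair not in visuals.edge_thickness:
            raise ValueError(f"visuals missing thickness for edge {edge.pair!r}")

    if format == "gexf":
        payload = _to_gexf(network, layout, visuals)
    elif format == "graphml":
        payload = _to_graphml(network, layout, visuals)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'gexf' or 'graphml'")
    Path(path).write_bytes(payload)


_NODE_ATTRS = (
    ("category", "string"),
    ("keyword_count", "long"),
    ("weighted_degree", "double"),
    ("x", "double"),
    ("y", "double"),
    ("label_size", "double"),
)
_EDGE_ATTRS = (
    ("study_count", "long"),
    ("connectivity", "double"),
    ("thickness", "double"),
)


def _node_values(network, layout, visuals, name):
    node = network.node(name)
    x, y = layout.positions[name]
    return {
        "category": node.category,
        "keyword_count": str(node.keyword_count),
        "weighted_degree": _fmt(node.weighted_degree),
        "x": _fmt(x),
        "y": _fmt(y),
        "label_size": _fmt(visuals.label_size[name]),
    }


def _edge_values(visuals, edge):
    return {
        "study_count": str(edge.study_count),
        "connectivity": _fmt(edge.connectivity),
        "thickness": _fmt(visuals.edge_thickness[edge.pair]),
    }


def _serialize(root: ET.Element) -> bytes:
    ET.indent(root, space="  ")
    return ET.tostring(root, encoding="UTF-8", xml_declaration=True) + b"\n"


def _to_gexf(network, layout, visuals) -> bytes:
    root = ET.Element("gexf", {"xmlns": GEXF_NS, "xmlns:viz": GEXF_VIZ_NS, "version": "1.2"})
    graph = ET.SubElement(root, "graph", {"defaultedgetype": "undirected", "mode": "static"})

    node_attr_ids = {}
    attrs = ET.SubElement(graph, "attributes", {"class": "node"})
    for i, (title, kind) in enumerate(_NODE_ATTRS):
        ET.SubElement(attrs, "attribute", {"id": str(i), "title": title, "type": kind})
        node_attr_ids[title] = str(i)
    edge_attr_ids = {}
    attrs = ET.SubElement(graph, "attributes", {"class": "edge"})
    for i, (title, kind) in enumerate(_EDGE_ATTRS):
        ET.SubElement(attrs, "attribute", {"id": str(i), "title": title, "type": kind})
        edge_attr_ids[title] = str(i)

    nodes_el = ET.SubElement(graph, "nodes")
    for name in layout.order:
        node_el = ET.SubElement(nodes_el, "node", {"id": name, "label": name})
        attv = ET.SubElement(node_el, "attvalues")
        for title, value in _node_values(network, layout, visuals, name).items():
            ET.SubElement(attv, "attvalue", {"for": node_attr_ids[title], "value": value})
        x, y = layout.positions[name]
        ET.SubElement(
            node_el, "viz:position", {"x": _fmt(x), "y": _fmt(y), "z": "0"}
        )
        ET.SubElement(node_el, "viz:size", {"value": _fmt(visuals.label_size[name])})

    edges_el = ET.SubElement(graph, "edges")
    for i, edge in enumerate(sorted(network.edges, key=lambda e: e.pair)):
        edge_el = ET.SubElement(
            edges_el,
            "edge",
            {
                "id": f"e{i}",
                "source": edge.source,
                "target": edge.target,
                "weight": _fmt(edge.connectivity),
            },
        )
        attv = ET.SubElement(edge_el, "attvalues")
        for title, value in _edge_values(visuals, edge).items():
            ET.SubElement(attv, "attvalue", {"for": edge_attr_ids[title], "value": value})
    return _serialize(root)


def _to_graphml(network, layout, visuals) -> bytes:
    root = ET.Element("graphml", {"xmlns": GRAPHML_NS})
    key_ids = {}
    next_key = 0
    for domain, table in (("node", _NODE_ATTRS), ("edge", _EDGE_ATTRS + (("weight", "double"),))):
        for title, kind in table:
            kid = f"d{next_key}"
            next_key += 1
            key_ids[(domain, title)] = kid
            ET.SubElement(
                root,
                "key",
                {"id": kid, "for": domain, "attr.name": title, "attr.type": kind},
            )
    graph = ET.SubElement(root, "graph", {"id": "G", "edgedefault": "undirected"})
    for name in layout.order:
        node_el = ET.SubElement(graph, "node", {"id": name})
        for title, value in _node_values(network, layout, visuals, name).items():
            ET.SubElement(node_el, "data", {"key": key_ids[("node", title)]}).text = value
    for edge in sorted(network.edges, key=lambda e: e.pair):
        edge_el = ET.SubElement(graph, "edge", {"source": edge.source, "target": edge.target})
        values = _edge_values(visuals, edge)
        values["weight"] = _fmt(edge.connectivity)
        for title, value in values.items():
            ET.SubElement(edge_el, "data", {"key": key_ids[("edge", title)]}).text = value
    return _serialize(root)
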