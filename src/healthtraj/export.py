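"""Serialise the risk-annotated concept lattice as a weighted directed network.

Vertices are concepts (size attribute proportional to the smoothed risk,
colour encoding estimate reliability); directed edges are the covering moves
of the lattice, labelled with the signed percent risk change.  Rendering is
left to the consumer — the formats carry numeric size/width attributes, not
pixels.  Supported formats: GraphML, DOT and a node-link JSON dialect.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from ._util import HealthTrajError
from .fca import ConceptLattice
from .risk import RiskTable
from .trajectory import _edge_label

FORMATS = ("graphml", "dot", "json")

JSON_SCHEMA_VERSION = 1

#: Default render colours for the reliability classes.
STYLE = {"green": "#2ca02c", "red": "#d62728", "yellow": "#ffbf00"}

TOP_LABEL = "NO COMMON FACTORS"


class ExportError(HealthTrajError):
    """Unknown export format or inconsistent inputs."""


def to_networkx(lattice: ConceptLattice, risks: RiskTable) -> nx.DiGraph:
    """Weighted directed network of all nonempty-extent concepts.

    Node ids are ``c000, c001, ...`` in the deterministic (|intent|, intent)
    lattice order; every edge corresponds to a covering edge of the lattice.
    """
    graph = nx.DiGraph(schema_version=JSON_SCHEMA_VERSION)
    node_id: dict[frozenset, str] = {}
    counter = 0
    for concept in lattice.concepts:
        risk = risks.get(concept)
        if risk is None:
            continue
        nid = f"c{counter:03d}"
        counter += 1
        node_id[concept.intent] = nid
        label = ";".join(sorted(concept.intent)) if concept.intent else TOP_LABEL
        graph.add_node(
            nid,
            label=label,
            intent=";".join(sorted(concept.intent)),
            n=risk.n,
            k=risk.k,
            p_adj=risk.p_adj,
            share=risk.share,
            size=risk.p_adj,
            color=risk.reliability,
            hex=STYLE[risk.reliability],
        )
    for i, j in sorted(lattice.edges):
        parent, child = lattice.concepts[i], lattice.concepts[j]
        if parent.intent not in node_id or child.intent not in node_id:
            continue
        label = _edge_label(risks[parent].p_adj, risks[child].p_adj)
        graph.add_edge(
            node_id[parent.intent],
            node_id[child.intent],
            added=";".join(sorted(child.intent - parent.intent)),
            label=label,
            width=abs(label),
            improving=label > 0,
        )
    return graph


def _to_dot(graph: nx.DiGraph) -> str:
    lines = ["digraph lattice {"]
    for nid in sorted(graph.nodes):
        a = graph.nodes[nid]
        lines.append(
            f'  {nid} [label="{a["label"]}\\nn={a["n"]} p={100 * a["p_adj"]:.2f}%", '
            f'color="{a["hex"]}", n={a["n"]}, p_adj={a["p_adj"]:.6f}, '
            f'reliability="{a["color"]}"];'
        )
    for u, v in sorted(graph.edges):
        a = graph.edges[u, v]
        lines.append(
            f'  {u} -> {v} [label="{a["label"]}%", added="{a["added"]}", '
            f"penwidth={max(1, a['width'] // 10)}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def _to_json(graph: nx.DiGraph) -> str:
    doc = {
        "schema_version": JSON_SCHEMA_VERSION,
        "directed": True,
        "style": STYLE,
        "nodes": [
            {"id": nid, **graph.nodes[nid]} for nid in sorted(graph.nodes)
        ],
        "edges": [
            {"source": u, "target": v, **graph.edges[u, v]}
            for u, v in sorted(graph.edges)
        ],
    }
    return json.dumps(doc, indent=1)


def export_network(
    lattice: ConceptLattice,
    risks: RiskTable,
    format: str = "graphml",
    path: str | Path | None = None,
) -> str:
    """Serialise the lattice network; returns the document text.

    A pure function of its inputs: identical (lattice, risks, format) give
    byte-identical output.  Unknown formats raise :class:`ExportError`.
    """
    if format not in FORMATS:
        raise ExportError(
            f"unknown format {format!r}; supported formats: {', '.join(FORMATS)}"
        )
    graph = to_networkx(lattice, risks)
    if format == "graphml":
        document = "\n".join(nx.generate_graphml(graph)) + "\n"
    elif format == "dot":
        document = _to_dot(graph)
    else:
        document = _to_json(graph)
    if path is not None:
        Path(path).write_text(document, encoding="utf-8")
    return document
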