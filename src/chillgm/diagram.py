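"""Three-layer path diagrams from a fitted graphical model.

A path diagram has one node per variable, ranked by causal layer (1 cause,
2 intermediate effect, 3 effect), and one link per retained edge of the
selected model.  Links spanning layers are drawn as arrows from the lower
layer to the higher one -- the declared layer ordering is the only source
of direction the method offers; links within a layer stay undirected.
Each link carries the partial correlation of the fitted model.

Exports: Graphviz DOT, GraphML, and a JSON schema that round-trips through
:func:`diagram_from_json`.  All exports are deterministic (fixed node and
edge ordering), so identical inputs produce byte-identical documents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx

from .covselect import FittedModel, GraphModel
from .datasets import VariableSpec

__all__ = [
    "DiagramNode",
    "DiagramLink",
    "PathDiagram",
    "build_diagram",
    "export_diagram",
    "diagram_from_json",
    "DIAGRAM_FORMATS",
]

DIAGRAM_FORMATS = ("dot", "graphml", "json")


@dataclass(frozen=True)
class DiagramNode:
    name: str
    layer_rank: int  # 1 cause, 2 intermediate, 3 effect
    unit: str


@dataclass(frozen=True)
class DiagramLink:
    source: str
    target: str
    partial_r: float
    directed: bool

    @property
    def sign(self) -> int:
        return 1 if self.partial_r >= 0 else -1


@dataclass
class PathDiagram:
    nodes: list
    links: list

    @property
    def node_names(self) -> list:
        return [node.name for node in self.nodes]


def build_diagram(model: GraphModel, fit: FittedModel) -> PathDiagram:
    """Assemble the path diagram for a selected model and its fitted matrix.

    The model supplies the retained edges and layer ranks; the fit supplies
    each edge's partial correlation.  Model and fit must agree on variables
    and zero set.
    """
    names = model.variable_names
    if names != fit.variable_names:
        raise ValueError("model and fit disagree on the variable set")
    if frozenset(model.zero_set) != frozenset(fit.zero_set):
        raise ValueError("model and fit disagree on the zero-constrained pairs")
    ranks = {}
    nodes = []
    for var in model.variables:
        if not isinstance(var, VariableSpec) or var.rank is None:
            raise ValueError("every variable needs a layer label to be diagrammed")
        ranks[var.name] = var.rank
        nodes.append(DiagramNode(var.name, var.rank, var.unit))

    partial = fit.partial_matrix()
    links = []
    for a, b in sorted(model.edges):
        value = float(partial.loc[a, b])
        if ranks[a] == ranks[b]:
            links.append(DiagramLink(a, b, value, directed=False))
        elif ranks[a] < ranks[b]:
            links.append(DiagramLink(a, b, value, directed=True))
        else:
            links.append(DiagramLink(b, a, value, directed=True))
    return PathDiagram(nodes, links)


def export_diagram(diagram: PathDiagram, format: str = "dot") -> str:
    """Serialize a diagram as ``"dot"``, ``"graphml"`` or ``"json"`` text."""
    if format == "dot":
        return _to_dot(diagram)
    if format == "graphml":
        return _to_graphml(diagram)
    if format == "json":
        return _to_json(diagram)
    raise ValueError(f"unknown diagram format {format!r}; choose from {DIAGRAM_FORMATS}")


def _to_dot(diagram: PathDiagram) -> str:
    # Positive partials solid, negative dashed; width scales with |partial r|.
    lines = ["digraph path_diagram {", "  rankdir=TB;", "  node [shape=box];"]
    by_rank = {}
    for node in diagram.nodes:
        by_rank.setdefault(node.layer_rank, []).append(node)
    for rank in sorted(by_rank):
        lines.append(f"  {{ rank=same;  // layer {rank}")
        for node in by_rank[rank]:
            lines.append(
                f'    "{node.name}" [label="{node.name}\\n({node.unit})", layer={rank}];'
            )
        lines.append("  }")
    for link in diagram.links:
        style = "solid" if link.sign > 0 else "dashed"
        width = round(0.5 + 2.5 * abs(link.partial_r), 2)
        attrs = [
            f'label="{link.partial_r:.4f}"',
            f"style={style}",
            f"penwidth={width}",
        ]
        if not link.directed:
            attrs.append("dir=none")
        lines.append(f'  "{link.source}" -> "{link.target}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _to_graphml(diagram: PathDiagram) -> str:
    graph = nx.DiGraph()
    for node in diagram.nodes:
        graph.add_node(node.name, layer=node.layer_rank, unit=node.unit)
    for link in diagram.links:
        graph.add_edge(
            link.source,
            link.target,
            weight=round(link.partial_r, 4),
            directed=link.directed,
            sign=link.sign,
        )
    return "\n".join(nx.generate_graphml(graph, named_key_ids=True)) + "\n"


def _to_json(diagram: PathDiagram) -> str:
    doc = {
        "nodes": [
            {"name": n.name, "layer": n.layer_rank, "unit": n.unit}
            for n in diagram.nodes
        ],
        "links": [
            {
                "source": l.source,
                "target": l.target,
                "partial_r": round(l.partial_r, 4),
                "directed": l.directed,
                "sign": l.sign,
            }
            for l in diagram.links
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def diagram_from_json(text: str) -> PathDiagram:
    """Inverse of the JSON export (weights carry the 4-d.p. rounding)."""
    doc = json.loads(text)
    nodes = [DiagramNode(d["name"], d["layer"], d["unit"]) for d in doc["nodes"]]
    links = [
        DiagramLink(d["source"], d["target"], d["partial_r"], d["directed"])
        for d in doc["links"]
    ]
    return PathDiagram(nodes, links)
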