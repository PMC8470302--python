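"""Directed rule-network construction and export.

The top rules (by IS) become a directed graph: block nodes sized by the
largest support of any incident rule, edges weighted by support, lift
and IS.  A rule with a multi-block antecedent is rendered through an
auxiliary *junction* node (one in-edge per antecedent block, one
out-edge to the consequent) — the bipartite convention used by basket-
analysis visualisers, since plain graph formats have no hyperedges.

Color/size mapping is metadata only: the numeric attributes travel in
the export and rendering is left to downstream viewers (an optional
matplotlib helper is provided).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .mining import AssociationRule

__all__ = ["build_rule_graph", "export_graph", "import_graph", "plot_rule_graph"]


def build_rule_graph(rules: Sequence[AssociationRule], max_rules: int = 20) -> nx.DiGraph:
    """Graph of the top ``max_rules`` rules (input order preserved)."""
    graph = nx.DiGraph(n_rules=0)
    for rule in list(rules)[: max(max_rules, 0)]:
        m = rule.metrics
        attrs = {"support": m.support, "lift": m.lift, "is_scale": m.is_scale}
        for block in (*rule.antecedent, rule.consequent):
            _touch_node(graph, block, m.support, kind="block")
        if len(rule.antecedent) == 1:
            graph.add_edge(rule.antecedent[0], rule.consequent, **attrs)
        else:
            junction = ",".join(rule.antecedent)
            _touch_node(graph, junction, m.support, kind="junction")
            for block in rule.antecedent:
                graph.add_edge(block, junction, **attrs)
            graph.add_edge(junction, rule.consequent, **attrs)
        graph.graph["n_rules"] += 1
    return graph


def _touch_node(graph: nx.DiGraph, node: str, support: float, kind: str) -> None:
    if node in graph:
        graph.nodes[node]["node_support"] = max(graph.nodes[node]["node_support"], support)
    else:
        graph.add_node(node, node_support=support, kind=kind)


_FORMATS = ("graphml", "dot", "json")


def export_graph(graph: nx.DiGraph, path, format: str = "graphml") -> Path:
    """Serialize with all node/edge attributes; GraphML keys are typed."""
    fmt = format.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {_FORMATS}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "json":
        path.write_text(json.dumps(nx.node_link_data(graph, edges="edges"), indent=1))
    else:
        path.write_text(_to_dot(graph))
    return path


def import_graph(path, format: str = "graphml") -> nx.DiGraph:
    fmt = format.lower()
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "json":
        data = json.loads(Path(path).read_text())
        return nx.node_link_graph(data, edges="edges")
    raise ValueError(f"cannot re-import format {format!r}")


def _dot_quote(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def _to_dot(graph: nx.DiGraph) -> str:
    # Minimal writer: graphviz layout engines are presentation, not contract.
    lines = ["digraph rules {"]
    for node, attrs in graph.nodes(data=True):
        lines.append(
            f"  {_dot_quote(node)} [node_support={attrs['node_support']:.3f}, "
            f"kind={_dot_quote(attrs['kind'])}];"
        )
    for u, v, attrs in graph.edges(data=True):
        lines.append(
            f"  {_dot_quote(u)} -> {_dot_quote(v)} "
            f"[label=\"lift={attrs['lift']:.3f}\", support={attrs['support']:.3f}, "
            f"is_scale={attrs['is_scale']:.3f}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def plot_rule_graph(graph: nx.DiGraph, path=None, seed: int = 0):
    """Static rendering: node size ~ support, edge darkness ~ lift."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    if graph.number_of_nodes():
        pos = nx.spring_layout(graph, seed=seed)
        supports = [graph.nodes[v]["node_support"] for v in graph]
        max_s = max(supports) or 1.0
        lifts = [d["lift"] for _, _, d in graph.edges(data=True)]
        max_l = max(lifts) if lifts else 1.0
        nx.draw_networkx(
            graph,
            pos,
            ax=ax,
            node_size=[300 + 2700 * s / max_s for s in supports],
            node_color="#9ecae1",
            edge_color=[0.25 + 0.75 * l / max_l for l in lifts],
            edge_cmap=plt.cm.Greys,
            edge_vmin=0.0,
            edge_vmax=1.0,
            font_size=7,
        )
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return Path(path)
    return fig
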