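"""Graphviz DOT emission for circuit query results.

Nodes are labeled ``label (CURIE)``; synapse nodes (structures where a
pre-ganglionic terminal meets a post-ganglionic soma) get a highlighted
style.  Exact colors and shapes are style configuration, not semantics.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .queries import CircuitEdgeRow

DEFAULT_STYLE: dict[str, str] = {
    "node_shape": "box",
    "node_style": "rounded",
    "synapse_shape": "ellipse",
    "synapse_style": "filled",
    "synapse_fillcolor": "lightblue",
    "rankdir": "LR",
}


def _quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def circuit_to_dot(
    rows: Iterable[CircuitEdgeRow],
    name: str = "circuit",
    style: Optional[dict[str, str]] = None,
) -> str:
    """Render circuit edges as a DOT digraph.

    One node per anatomical structure (merged across populations), one
    directed edge per pathway hop annotated with the population id; edges
    flagged as synapses mark their target node with the synapse style.
    """
    style = {**DEFAULT_STYLE, **(style or {})}
    rows = list(rows)
    nodes: dict[str, str] = {}
    synapse_nodes: set[str] = set()
    for row in rows:
        for labeled in (row.v1, row.v2):
            key = labeled.curie.render()
            nodes.setdefault(key, f"{labeled.label} ({key})")
        if row.is_synapse:
            synapse_nodes.add(row.v2.curie.render())

    lines = [f"digraph {_quote(name)} {{"]
    lines.append(f"  rankdir={style['rankdir']};")
    lines.append(
        f"  node [shape={style['node_shape']}, style={_quote(style['node_style'])}];"
    )
    for key in sorted(nodes):
        attrs = f"label={_quote(nodes[key])}"
        if key in synapse_nodes:
            attrs += (
                f", shape={style['synapse_shape']}, style={_quote(style['synapse_style'])}"
                f", fillcolor={_quote(style['synapse_fillcolor'])}, synapse={_quote('true')}"
            )
        lines.append(f"  {_quote(key)} [{attrs}];")
    for row in rows:
        attrs = f"label={_quote(row.population.render())}"
        if row.is_synapse:
            attrs += ", penwidth=2"
        lines.append(
            f"  {_quote(row.v1.curie.render())} -> {_quote(row.v2.curie.render())} [{attrs}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
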