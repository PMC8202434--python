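"""Readers and writers for the plain-text interchange formats.

GMT gene sets, TSV edge lists, GraphML / SIF network exports, and small
JSON artifacts. All writers are deterministic (sorted where order is not
meaningful) so pipeline outputs are byte-stable under a fixed seed.
"""

from __future__ import annotations

import json

import networkx as nx
import pandas as pd


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = "\t".join(sets[name])
            fh.write(f"{name}\t{description}\t{genes}\n")


def write_network_graphml(net: nx.DiGraph, path) -> None:
    """GraphML with full node/edge attributes, nodes in sorted order."""
    ordered = nx.DiGraph(**net.graph)
    for n in sorted(net.nodes):
        ordered.add_node(n, **{k: _graphml_safe(v) for k, v in net.nodes[n].items()})
    for u, v in sorted(net.edges):
        ordered.add_edge(u, v, **{k: _graphml_safe(w) for k, w in net[u][v].items()})
    nx.write_graphml(ordered, path)


def _graphml_safe(v):
    if v is None:
        return ""
    return v


def write_network_sif(net: nx.DiGraph, path, relationship: str = "regulates") -> None:
    """SIF: one ``tf relationship target`` row per edge; the edge sign is
    used as the relationship when known."""
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            rel = net[u][v].get("sign", "unknown")
            rel = relationship if rel in ("unknown", None, "") else rel
            fh.write(f"{u}\t{rel}\t{v}\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
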