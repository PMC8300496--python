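"""Signed directed causal networks.

Repeated links between the same directed concept pair are pooled into a
single edge whose weight is the arithmetic mean of the constituent link
weights — opposing reports therefore cancel toward zero — while the
evidence count (number of pooled links) is kept so users can re-weight.
Edges with mean weight exactly zero are retained and flagged rather than
removed: a contested interaction is information, not absence of one.

Ego subnetworks support stepwise, data-driven hypothesis building around a
focal component (e.g. *reindeer*): by default reachability treats edges as
undirected, collecting the components affecting and affected by the focal
one; directed-only modes are available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from difflib import get_close_matches
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import FocalNodeError, ValidationError
from .extraction import CausalLink

EDGE_COLUMNS = ("driver", "target", "mean_weight", "evidence_count")
REACHABILITY_MODES = ("both", "out", "in")

#: provenance triple kept per pooled link
Provenance = tuple[str, int, str]  # (doc_id, sentence_index, sentence_text)


@dataclass(frozen=True)
class EdgeAggregate:
    """One pooled directed edge: mean signed weight over its evidence."""

    driver: str
    target: str
    mean_weight: float
    evidence_count: int
    provenance: tuple[Provenance, ...] = ()

    def __post_init__(self) -> None:
        if self.evidence_count < 1:
            raise ValidationError("evidence_count must be >= 1")

    @property
    def is_self_loop(self) -> bool:
        return self.driver == self.target


def aggregate(links: Iterable[CausalLink]) -> list[EdgeAggregate]:
    """Pool links by exact directed (driver, target) pair, averaging the
    signed weights; provenances concatenated in input order. Direction
    matters: (A→B) and (B→A) stay distinct edges."""
    groups: dict[tuple[str, str], list[CausalLink]] = {}
    for link in links:
        groups.setdefault((link.driver, link.target), []).append(link)
    return [
        EdgeAggregate(
            driver=driver,
            target=target,
            mean_weight=sum(l.weight for l in members) / len(members),
            evidence_count=len(members),
            provenance=tuple((l.doc_id, l.sentence_index, l.sentence_text)
                             for l in members),
        )
        for (driver, target), members in groups.items()
    ]


@dataclass
class CausalNetwork:
    """Signed directed graph of aggregated causal edges.

    Thin wrapper around a :class:`networkx.DiGraph` whose edge attributes
    are ``mean_weight``, ``evidence_count`` and a JSON-encoded provenance
    list. Self-loops are permitted but flagged.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[EdgeAggregate]:
        return [
            EdgeAggregate(u, v, data["mean_weight"], data["evidence_count"],
                          tuple(tuple(p) for p in
                                json.loads(data.get("provenance", "[]"))))
            for u, v, data in self.graph.edges(data=True)
        ]

    @property
    def self_loops(self) -> list[tuple[str, str]]:
        return list(nx.selfloop_edges(self.graph))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalNetwork):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        mine = {(u, v): (d["mean_weight"], d["evidence_count"],
                         d.get("provenance", "[]"))
                for u, v, d in self.graph.edges(data=True)}
        theirs = {(u, v): (d["mean_weight"], d["evidence_count"],
                           d.get("provenance", "[]"))
                  for u, v, d in other.graph.edges(data=True)}
        return mine == theirs


def build_network(edges: Iterable[EdgeAggregate]) -> CausalNetwork:
    """Assemble aggregated edges into a network; the node set is the union
    of edge endpoints."""
    g = nx.DiGraph()
    for e in edges:
        g.add_edge(
            e.driver, e.target,
            mean_weight=float(e.mean_weight),
            evidence_count=int(e.evidence_count),
            provenance=json.dumps([list(p) for p in e.provenance]),
            self_loop=e.is_self_loop,
        )
    return CausalNetwork(g)


def network_from_links(links: Iterable[CausalLink]) -> CausalNetwork:
    return build_network(aggregate(links))


def ego_subnetwork(network: CausalNetwork, focal: str, depth: int = 1,
                   reachability: str = "both") -> CausalNetwork:
    """Subnetwork of all nodes within ``depth`` steps of ``focal``.

    ``reachability="both"`` (default) treats edges as undirected — the
    components affecting and affected by the focal one; ``"out"`` follows
    only outgoing edges, ``"in"`` only incoming. The edge set is every
    original directed edge with both endpoints retained.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if reachability not in REACHABILITY_MODES:
        raise ValidationError(
            f"reachability must be one of {REACHABILITY_MODES}")
    g = network.graph
    if focal not in g:
        hints = get_close_matches(focal, list(g.nodes), n=5)
        raise FocalNodeError(
            f"focal concept {focal!r} is not in the network"
            + (f"; nearest matches: {hints}" if hints else ""))
    if reachability == "both":
        search = g.to_undirected(as_view=True)
    elif reachability == "out":
        search = g
    else:
        search = g.reverse(copy=False)
    reached = {focal}
    frontier = {focal}
    for _ in range(depth):
        nxt = {n for u in frontier for n in search.neighbors(u)} - reached
        if not nxt:
            break
        reached |= nxt
        frontier = nxt
    return CausalNetwork(nx.DiGraph(g.subgraph(reached)))


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

GRAPH_FORMATS = ("graphml", "edgelist-csv", "dot")


def edges_to_frame(network: CausalNetwork) -> pd.DataFrame:
    rows = [
        {"driver": e.driver, "target": e.target,
         "mean_weight": e.mean_weight, "evidence_count": e.evidence_count}
        for e in network.edges
    ]
    return pd.DataFrame(rows, columns=list(EDGE_COLUMNS))


def _dot_escape(name: str) -> str:
    return '"' + name.replace("\\", "\\\\").replace('"', '\\"') + '"'


def export_graph(network: CausalNetwork, path: str | Path,
                 format: str = "graphml") -> Path:
    """Write the network as GraphML (lossless, re-importable), edge-list CSV
    or DOT for external rendering."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network.graph, path)
    elif format == "edgelist-csv":
        edges_to_frame(network).to_csv(path, index=False, encoding="utf-8")
    elif format == "dot":
        lines = ["digraph causal {"]
        for node in network.graph.nodes:
            lines.append(f"  {_dot_escape(node)};")
        for u, v, d in network.graph.edges(data=True):
            style = "solid" if d["mean_weight"] >= 0 else "dashed"
            lines.append(
                f"  {_dot_escape(u)} -> {_dot_escape(v)} "
                f'[label="{d["mean_weight"]:g}", style={style}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", "utf-8")
    else:
        raise ValidationError(
            f"unknown graph format {format!r}; expected one of {GRAPH_FORMATS}")
    return path


def import_graphml(path: str | Path) -> CausalNetwork:
    """Re-import a GraphML export; round-trips the network exactly."""
    g = nx.read_graphml(path)
    out = nx.DiGraph()
    out.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v,
                     mean_weight=float(d["mean_weight"]),
                     evidence_count=int(d["evidence_count"]),
                     provenance=d.get("provenance", "[]"),
                     self_loop=bool(d.get("self_loop", u == v)))
    return CausalNetwork(out)
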