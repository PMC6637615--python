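"""Phase 1: building the weighted influence graph (G1).

Starting from the observed effect entities (the roots), the network is
explored outward with a Dijkstra-style priority-queue search over the priced
influence edges, out to a maximum cumulative cost ``c_max``.  Each node
tracks both its minimum cost to *any* root (C) and its minimum cost to each
individual root (the PC map); PC updates are propagated recursively to
already-discovered descendants along strictly improving entries, and
improved nodes are re-queued so that late cost improvements can still create
nodes near the cutoff.  With non-negative edge costs this yields exact
multi-source and per-root shortest-path distances over the explored graph.

Node-creation rule: a new node N' is created only when C_N + cost(N->N') <
c_max.  Edges between two already-existing nodes are always recorded, even
when the path through them exceeds the cutoff.  Transcription-unit nodes are
created but never expanded (dead ends).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .influence_edges import InfluenceEdge, priced_influencers_of
from .network_model import Network

DEFAULT_C_MAX = 20.0
_EPS = 1e-9


@dataclass
class MetRegNode:
    id: str
    #: minimum-weight path cost from this node back to any root
    C: float
    #: per-root minimum path cost (root id -> cost)
    PC: dict[str, float] = field(default_factory=dict)


@dataclass
class MetRegGraph:
    roots: tuple[str, ...]
    c_max: float
    mode: str
    nodes: dict[str, MetRegNode] = field(default_factory=dict)
    #: edge key -> priced edge (stored in search direction X -> I)
    edges: dict[tuple, InfluenceEdge] = field(default_factory=dict)
    #: adjacency: from_node -> list of edge keys
    out_edges: dict[str, list[tuple]] = field(default_factory=dict)
    input_entities: frozenset[str] = frozenset()

    def add_edge(self, edge: InfluenceEdge) -> None:
        if edge.key not in self.edges:
            self.edges[edge.key] = edge
            self.out_edges.setdefault(edge.from_node, []).append(edge.key)

    def edges_from(self, node: str) -> list[InfluenceEdge]:
        return [self.edges[k] for k in self.out_edges.get(node, ())]

    def path_cost(self, root: str, node: str) -> Optional[float]:
        n = self.nodes.get(node)
        return None if n is None else n.PC.get(root)


def build_metreg_graph(
    effects: Iterable[str],
    net: Network,
    input_entities: Iterable[str] = (),
    c_max: float = DEFAULT_C_MAX,
    mode: str = "directed",
    sign_policy: Optional[Mapping[str, str]] = None,
) -> MetRegGraph:
    """Build the influence graph G1 rooted at the effect entities.

    ``input_entities`` are all user-supplied targets (conditions and
    effects); edges whose influencer belongs to this set cost the flat 0.1
    override.  The effect entities are always included.
    """
    if c_max <= 0:
        raise ValueError("c_max must be positive")
    roots = []
    for e in effects:
        r = net.logical_node_of(e)
        if r not in roots:
            roots.append(r)
    if not roots:
        raise ValueError("effects must be non-empty")
    inputs = frozenset(net.logical_node_of(e) for e in input_entities) | frozenset(
        roots
    )

    g = MetRegGraph(
        roots=tuple(roots),
        c_max=float(c_max),
        mode=mode,
        input_entities=inputs,
    )
    queue: list[tuple[float, str]] = []
    expanded_at: dict[str, float] = {}

    for r in roots:
        g.nodes[r] = MetRegNode(id=r, C=0.0, PC={r: 0.0})
        heapq.heappush(queue, (0.0, r))

    def propagate(start: str, updated_roots: set[str]) -> None:
        """Push strictly improving PC entries down already-stored edges."""
        stack = [(start, frozenset(updated_roots))]
        while stack:
            nid, roots_upd = stack.pop()
            node = g.nodes[nid]
            for edge in g.edges_from(nid):
                child = g.nodes.get(edge.to_node)
                if child is None:
                    continue
                improved: set[str] = set()
                for r in roots_upd:
                    cand = node.PC[r] + edge.cost
                    old = child.PC.get(r)
                    if old is None or cand < old - _EPS:
                        child.PC[r] = cand
                        improved.add(r)
                if improved:
                    new_c = min(child.PC.values())
                    if new_c < child.C - _EPS:
                        child.C = new_c
                        if child.id not in net.transcription_units:
                            heapq.heappush(queue, (new_c, child.id))
                    stack.append((child.id, frozenset(improved)))

    def relax_existing(node: MetRegNode, edge: InfluenceEdge) -> None:
        """Add an edge between two existing nodes and minimise PC entries."""
        tgt = g.nodes[edge.to_node]
        g.add_edge(edge)
        improved: set[str] = set()
        for r, pc in node.PC.items():
            cand = pc + edge.cost
            old = tgt.PC.get(r)
            if old is None or cand < old - _EPS:
                tgt.PC[r] = cand
                improved.add(r)
        if improved:
            new_c = min(tgt.PC.values())
            if new_c < tgt.C - _EPS:
                tgt.C = new_c
                if tgt.id not in net.transcription_units:
                    heapq.heappush(queue, (new_c, tgt.id))
            propagate(tgt.id, improved)

    # Edges whose target failed the creation cutoff are deferred: the target
    # may still come into existence later through a cheaper route, and the
    # final graph must not depend on expansion order.
    deferred: list[tuple[str, InfluenceEdge]] = []

    while True:
        while queue:
            c, nid = heapq.heappop(queue)
            node = g.nodes[nid]
            if c > node.C + _EPS:
                continue  # stale entry
            prev = expanded_at.get(nid)
            if prev is not None and prev <= node.C + _EPS:
                continue  # already expanded at this (or a better) cost
            expanded_at[nid] = node.C
            if nid in net.transcription_units:
                continue  # dead end: never expanded

            for edge in priced_influencers_of(
                nid, net, g.mode, g.input_entities, sign_policy
            ):
                if edge.to_node not in g.nodes:
                    if node.C + edge.cost < g.c_max - _EPS:
                        tgt = MetRegNode(
                            id=edge.to_node,
                            C=node.C + edge.cost,
                            PC={r: pc + edge.cost for r, pc in node.PC.items()},
                        )
                        g.nodes[edge.to_node] = tgt
                        g.add_edge(edge)
                        if edge.type != "transcription-unit":
                            heapq.heappush(queue, (tgt.C, tgt.id))
                    else:
                        deferred.append((nid, edge))
                else:
                    relax_existing(node, edge)
        pending = [d for d in deferred if d[1].to_node in g.nodes]
        if not pending:
            break
        deferred = [d for d in deferred if d[1].to_node not in g.nodes]
        for nid, edge in pending:
            relax_existing(g.nodes[nid], edge)
    return g


def write_graph_tsv(g: MetRegGraph, out_dir: str | Path) -> list[Path]:
    """Dump G1 as an edge-list TSV and a node TSV (one PC column per root)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edge_path = out / "g1_edges.tsv"
    with edge_path.open("w", encoding="utf-8") as fh:
        fh.write("from\tto\ttype\tcost\tsign\tvia\n")
        for key in sorted(g.edges, key=lambda k: (k[0], k[2], k[3], k[1])):
            e = g.edges[key]
            fh.write(
                f"{e.from_node}\t{e.to_node}\t{e.type}\t{e.cost:.6g}\t{e.sign}\t"
                f"{e.via[0]}:{e.via[1]}\n"
            )
    node_path = out / "g1_nodes.tsv"
    roots = list(g.roots)
    with node_path.open("w", encoding="utf-8") as fh:
        fh.write("id\tC\t" + "\t".join(f"PC[{r}]" for r in roots) + "\n")
        for nid in sorted(g.nodes):
            n = g.nodes[nid]
            cols = [
                f"{n.PC[r]:.6g}" if r in n.PC else "" for r in roots
            ]
            fh.write(f"{nid}\t{n.C:.6g}\t" + "\t".join(cols) + "\n")
    return [edge_path, node_path]
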