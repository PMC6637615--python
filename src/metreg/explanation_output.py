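"""Phase 3: assembling and exporting the explanation graph (G3).

The filtered graph G2 is partitioned into two groups: nodes directly
associated with metabolic reactions (as reactants, products or enzymes of a
reaction underlying a G2 edge) and all others.  Each group splits into its
connected components.  Metabolic components become *temporary pathways*:
their reactions are ordered by shared substrates and drawn reactant ->
product, forcing in primary substrates that are absent from G2 (a reaction
cannot be drawn without both sides) while suppressing side metabolites and
enzymes outside G2.  Regulatory components are copied node-for-node.

The result is exported with full style annotation (arrowhead class per
influence type, colour per sign, highlight and direction-of-change classes
per node) as DOT, GraphML or a documented JSON explanation document; pixel
layout is delegated to the rendering tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from .influence_edges import REACTION_TYPES, InfluenceEdge
from .metreg_build import MetRegGraph
from .network_model import Network, Reaction
from .path_filter import (
    FilteredGraph,
    TargetSpec,
    filter_directed,
    filter_undirected,
)

#: Arrowhead class per influence type (total mapping).
ARROWHEAD_BY_TYPE: dict[str, str] = {
    "reactant-of-producing": "normal",
    "reactant-of-consuming": "normal",
    "product-of-consuming": "normal",
    "enzyme-of-producing": "normal",
    "enzyme-of-consuming": "normal",
    "transporter": "odot",
    "enzyme-activator": "vee",
    "enzyme-inhibitor": "tee",
    "cofactor": "diamond",
    "transcriptional-regulator": "empty",
    "translational-regulator": "empty",
    "sigma-factor": "invempty",
    "complex-component": "dot",
    "transcription-unit": "none",
}

#: Edge colour: chemical-reaction edges draw black; regulatory edges colour
#: by sign (activation green, inhibition red, ambiguous grey).
SIGN_COLOR = {"+": "green", "-": "red", "ambiguous": "gray40"}


def edge_style(edge: InfluenceEdge) -> tuple[str, str]:
    """(arrowhead class, colour class) — a total function of type x sign."""
    arrow = ARROWHEAD_BY_TYPE[edge.type]
    color = "black" if edge.type in REACTION_TYPES else SIGN_COLOR[edge.sign]
    return arrow, color


@dataclass(frozen=True)
class TempPathway:
    """A display-time chain of reactions for one metabolic component."""

    reactions: tuple[str, ...]
    display_nodes: frozenset[str]
    suppressed: frozenset[str]


@dataclass(frozen=True)
class ExplanationComponent:
    kind: str  # "metabolic" | "regulatory"
    nodes: tuple[str, ...]
    edge_keys: tuple[tuple, ...]
    pathway: Optional[TempPathway] = None
    #: layout hint: smaller rank drawn closer to the effect roots
    rank: int = 0


@dataclass
class ExplanationGraph:
    components: tuple[ExplanationComponent, ...]
    #: G2 edges whose endpoints fall in different components
    cross_edges: tuple[tuple, ...]
    edges: dict[tuple, InfluenceEdge]
    node_styles: dict[str, dict[str, str]]
    edge_styles: dict[tuple, dict[str, str]]
    node_labels: dict[str, str]


def _reaction_ids_of(g2: FilteredGraph) -> set[str]:
    return {
        e.via[0] for e in g2.edges.values() if e.type in REACTION_TYPES
    }


def _reaction_node_map(net: Network, reaction_ids: Iterable[str]) -> dict[str, set[str]]:
    """reaction id -> logical nodes directly associated with it."""
    out = {}
    for rid in reaction_ids:
        rxn = net.reactions[rid]
        out[rid] = {
            net.logical_node_of(e) for e in rxn.substrates() + rxn.enzymes
        }
    return out


def partition_components(
    g2: FilteredGraph, net: Network
) -> tuple[list[set[str]], list[set[str]]]:
    """Split G2 nodes into metabolic and regulatory groups, each further
    divided into connected components under the G2 edges within the group."""
    rxn_nodes = _reaction_node_map(net, _reaction_ids_of(g2))
    metabolic = {n for nodes in rxn_nodes.values() for n in nodes} & g2.nodes
    regulatory = g2.nodes - metabolic

    def components(group: set[str]) -> list[set[str]]:
        ug = nx.Graph()
        ug.add_nodes_from(group)
        for e in g2.edges.values():
            if e.from_node in group and e.to_node in group:
                ug.add_edge(e.from_node, e.to_node)
        comps = [set(c) for c in nx.connected_components(ug)]
        return sorted(comps, key=lambda c: min(c))

    return components(metabolic), components(regulatory)


def _primary_substrates(
    rxn: Reaction,
    net: Network,
    g2_nodes: set[str],
    chain_shared: set[str],
) -> tuple[set[str], set[str]]:
    """(primary, side) logical substrate sets for one displayed reaction.

    Primary substrates are those on a G2 path through the reaction or shared
    with an adjacent reaction in the chain; each side of the reaction keeps
    at least one primary substrate so the reaction can be drawn.  Everything
    else — including ubiquitous co-substrates — is a side metabolite.
    """
    primary: set[str] = set()
    side: set[str] = set()
    for side_ids in (rxn.reactants, rxn.products):
        logicals = []
        for s in side_ids:
            ln = net.logical_node_of(s)
            if ln not in logicals:
                logicals.append(ln)
        chosen = [
            ln
            for ln in logicals
            if not net.is_ubiquitous(ln) and (ln in g2_nodes or ln in chain_shared)
        ]
        if not chosen:
            non_ubiq = [ln for ln in logicals if not net.is_ubiquitous(ln)]
            pool = non_ubiq or logicals
            chosen = [sorted(pool)[0]] if pool else []
        primary.update(chosen)
        side.update(ln for ln in logicals if ln not in primary)
    return primary, side - primary


def assemble_temp_pathway(
    component: set[str], g2: FilteredGraph, net: Network
) -> TempPathway:
    """Assemble the reactions underlying a metabolic component into an
    ordered temporary pathway, forcing in absent primary substrates."""
    rxn_nodes = _reaction_node_map(net, _reaction_ids_of(g2))
    rids = sorted(
        rid for rid, nodes in rxn_nodes.items() if nodes & component
    )
    # chain reactions by shared non-ubiquitous substrates
    adj = nx.Graph()
    adj.add_nodes_from(rids)
    subs = {
        rid: {
            net.logical_node_of(s)
            for s in net.reactions[rid].substrates()
            if not net.is_ubiquitous(net.logical_node_of(s))
        }
        for rid in rids
    }
    for i, a in enumerate(rids):
        for b in rids[i + 1 :]:
            if subs[a] & subs[b]:
                adj.add_edge(a, b)
    order: list[str] = []
    for comp in sorted(nx.connected_components(adj), key=min):
        start = min(comp, key=lambda r: (adj.degree(r), r))
        order.extend(nx.dfs_preorder_nodes(adj.subgraph(comp), source=start))

    display: set[str] = set(component)
    suppressed: set[str] = set()
    for i, rid in enumerate(order):
        shared: set[str] = set()
        if i > 0:
            shared |= subs[order[i - 1]] & subs[rid]
        if i + 1 < len(order):
            shared |= subs[order[i + 1]] & subs[rid]
        primary, side = _primary_substrates(
            net.reactions[rid], net, g2.nodes, shared
        )
        display |= primary
        suppressed |= {ln for ln in side if ln not in g2.nodes}
        suppressed |= {
            net.logical_node_of(e)
            for e in net.reactions[rid].enzymes
            if net.logical_node_of(e) not in g2.nodes
        }
    suppressed -= display
    return TempPathway(
        reactions=tuple(order),
        display_nodes=frozenset(display),
        suppressed=frozenset(suppressed),
    )


def build_explanation_graph(
    g2: FilteredGraph,
    net: Network,
    target_specs: Sequence[TargetSpec] = (),
    cover: Iterable[str] = (),
) -> ExplanationGraph:
    """Deterministic assembly of the styled explanation graph."""
    met_comps, reg_comps = partition_components(g2, net)
    cover_set = set(cover)
    target_dirs = {t.entity: t.direction for t in target_specs}
    target_set = set(target_dirs)

    components: list[ExplanationComponent] = []
    node_to_comp: dict[str, int] = {}

    def comp_rank(nodes: set[str]) -> int:
        # layout hint: components containing effect roots draw first
        return 0 if any(n in target_set for n in nodes) else 1

    all_display: set[str] = set()
    for comp in met_comps:
        pw = assemble_temp_pathway(comp, g2, net)
        nodes = tuple(sorted(comp | set(pw.display_nodes)))
        components.append(
            ExplanationComponent(
                "metabolic", nodes, (), pathway=pw, rank=comp_rank(comp)
            )
        )
        all_display.update(nodes)
    for comp in reg_comps:
        nodes = tuple(sorted(comp))
        components.append(
            ExplanationComponent("regulatory", nodes, (), rank=comp_rank(comp))
        )
        all_display.update(nodes)
    components.sort(key=lambda c: (c.rank, c.kind, c.nodes))
    for idx, comp in enumerate(components):
        for n in comp.nodes:
            node_to_comp.setdefault(n, idx)

    # attach each G2 edge to its component, or record it as a cross link
    comp_edges: dict[int, list[tuple]] = {i: [] for i in range(len(components))}
    cross: list[tuple] = []
    for key in sorted(g2.edges):
        e = g2.edges[key]
        ci, cj = node_to_comp.get(e.from_node), node_to_comp.get(e.to_node)
        if ci is not None and ci == cj:
            comp_edges[ci].append(key)
        else:
            cross.append(key)
    components = [
        ExplanationComponent(
            c.kind, c.nodes, tuple(comp_edges[i]), c.pathway, c.rank
        )
        for i, c in enumerate(components)
    ]

    node_styles: dict[str, dict[str, str]] = {}
    labels: dict[str, str] = {}
    for n in sorted(all_display):
        ent = net.entities.get(n)
        labels[n] = ent.display_name() if ent is not None else n
        if n in target_set:
            highlight = "target"
        elif n in cover_set:
            highlight = "cover"
        elif n not in g2.nodes:
            highlight = "forced"
        else:
            highlight = "plain"
        direction = target_dirs.get(n) or ""
        node_styles[n] = {"highlight": highlight, "direction": direction}

    edge_styles = {}
    for key in sorted(g2.edges):
        arrow, color = edge_style(g2.edges[key])
        edge_styles[key] = {"arrowhead": arrow, "color": color}

    return ExplanationGraph(
        components=tuple(components),
        cross_edges=tuple(cross),
        edges=dict(g2.edges),
        node_styles=node_styles,
        edge_styles=edge_styles,
        node_labels=labels,
    )


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------
_NODE_FILL = {
    "target": "gold",
    "cover": "orange",
    "forced": "white",
    "plain": "lightblue",
}
_DIR_COLOR = {"up": "darkgreen", "down": "red3", "": "black"}


def _dot_id(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _to_dot(g3: ExplanationGraph) -> str:
    lines = ["digraph explanation {", "  rankdir=LR;", "  node [shape=box];"]
    for idx, comp in enumerate(g3.components):
        lines.append(f"  subgraph cluster_{idx} {{")
        lines.append(f"    label={_dot_id(comp.kind)};")
        for n in comp.nodes:
            st = g3.node_styles[n]
            lines.append(
                f"    {_dot_id(n)} [label={_dot_id(g3.node_labels[n])}, "
                f"style=filled, fillcolor={_NODE_FILL[st['highlight']]}, "
                f"fontcolor={_DIR_COLOR[st['direction']]}];"
            )
        for key in comp.edge_keys:
            lines.append("    " + _dot_edge(g3, key))
        lines.append("  }")
    for key in g3.cross_edges:
        lines.append("  " + _dot_edge(g3, key))
    lines.append("}")
    return "\n".join(lines) + "\n"


def _dot_edge(g3: ExplanationGraph, key: tuple) -> str:
    e = g3.edges[key]
    st = g3.edge_styles[key]
    # drawn in influence direction I -> X (reverse of storage direction)
    return (
        f"{_dot_id(e.to_node)} -> {_dot_id(e.from_node)} "
        f"[arrowhead={st['arrowhead']}, color={st['color']}, "
        f"label={_dot_id(e.type)}];"
    )


def _to_graphml(g3: ExplanationGraph) -> str:
    g = nx.MultiDiGraph()
    for comp_idx, comp in enumerate(g3.components):
        for n in comp.nodes:
            st = g3.node_styles[n]
            g.add_node(
                n,
                label=g3.node_labels[n],
                component=str(comp_idx),
                component_kind=comp.kind,
                highlight=st["highlight"],
                direction=st["direction"],
            )
    for key in list(g3.cross_edges) + [
        k for comp in g3.components for k in comp.edge_keys
    ]:
        e = g3.edges[key]
        st = g3.edge_styles[key]
        g.add_edge(
            e.to_node,
            e.from_node,
            key=f"{e.type}|{e.via[0]}:{e.via[1]}",
            influence_type=e.type,
            sign=e.sign,
            cost=f"{e.cost:.6g}" if e.cost is not None else "",
            arrowhead=st["arrowhead"],
            color=st["color"],
        )
    # networkx's writer is deterministic given insertion order; normalise by
    # rebuilding with sorted nodes/edges
    h = nx.MultiDiGraph()
    h.add_nodes_from(sorted(g.nodes(data=True)))
    h.add_edges_from(sorted(g.edges(keys=True, data=True)))
    return "\n".join(nx.generate_graphml(h)) + "\n"


def _to_json(g3: ExplanationGraph) -> str:
    def edge_doc(key: tuple) -> dict:
        e = g3.edges[key]
        st = g3.edge_styles[key]
        return {
            "influencer": e.to_node,
            "influenced": e.from_node,
            "type": e.type,
            "sign": e.sign,
            "cost": e.cost,
            "via": list(e.via),
            "style": st,
        }

    doc = {
        "components": [
            {
                "kind": c.kind,
                "rank": c.rank,
                "nodes": list(c.nodes),
                "edges": [edge_doc(k) for k in c.edge_keys],
                "pathway": (
                    None
                    if c.pathway is None
                    else {
                        "reactions": list(c.pathway.reactions),
                        "display_nodes": sorted(c.pathway.display_nodes),
                        "suppressed": sorted(c.pathway.suppressed),
                    }
                ),
            }
            for c in g3.components
        ],
        "cross_edges": [edge_doc(k) for k in g3.cross_edges],
        "node_styles": {
            n: dict(g3.node_styles[n], label=g3.node_labels[n])
            for n in sorted(g3.node_styles)
        },
    }
    return json.dumps(doc, indent=1, sort_keys=True, ensure_ascii=False) + "\n"


def export_graph(g3: ExplanationGraph, fmt: str, path: str | Path) -> Path:
    """Write the explanation graph as DOT, GraphML or JSON (byte-stable)."""
    if fmt == "dot":
        text = _to_dot(g3)
    elif fmt == "graphml":
        text = _to_graphml(g3)
    elif fmt == "json":
        text = _to_json(g3)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    p = Path(path)
    p.write_text(text, encoding="utf-8")
    return p


def reselect_subset(
    g1: MetRegGraph,
    selected: Iterable[str],
    net: Network,
    conditions: Sequence[TargetSpec] = (),
    effects: Sequence[TargetSpec] = (),
    mode: str = "directed",
    offset: float = 2.0,
    max_paths: int = 25,
    use_parity: bool = True,
) -> tuple[FilteredGraph, ExplanationGraph]:
    """Re-run Phases 2-3 on the cached G1 for a subset of the targets.

    G1 is left untouched; only the filtered and explanation graphs are
    recreated.
    """
    sel = {net.logical_node_of(s) for s in selected}
    if not sel:
        raise ValueError("selection must be non-empty")
    known = {t.entity for t in list(conditions) + list(effects)}
    unknown = sel - known
    if unknown:
        raise KeyError(f"selection outside the original targets: {sorted(unknown)}")
    if mode == "directed":
        conds = [t for t in conditions if t.entity in sel]
        effs = [t for t in effects if t.entity in sel]
        g2 = filter_directed(g1, conds, effs, offset, max_paths, use_parity)
        g3 = build_explanation_graph(g2, net, list(effs) + list(conds))
        return g2, g3
    effs = [t for t in effects if t.entity in sel]
    cover, g2 = filter_undirected(
        g1, [t.entity for t in effs], offset, max_paths
    )
    g3 = build_explanation_graph(
        g2, net, effs, cover=[c.entity for c in cover]
    )
    return g2, g3
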