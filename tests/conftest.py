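"""Shared fixtures and independent oracles.

The oracle functions here deliberately avoid the package's own graph-search
code paths: graph distances come from networkx Dijkstra over an explicitly
enumerated priced edge set, and path enumeration is plain unpruned recursion.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pytest

from metreg import priced_influencers_of, toy_network

DATA = Path(__file__).parent / "data"
_EPS = 1e-9


@pytest.fixture(scope="session")
def toy():
    return toy_network()


@pytest.fixture(scope="session")
def toy_file() -> Path:
    return DATA / "toy_network.json"


# ----------------------------------------------------------------------
# oracles
# ----------------------------------------------------------------------
def full_priced_edges(net, mode, inputs):
    """The complete priced influence-edge set over every logical node."""
    seen, edges = set(), {}
    for eid in net.entities:
        node = net.logical_node_of(eid)
        if node in seen:
            continue
        seen.add(node)
        for e in priced_influencers_of(node, net, mode, frozenset(inputs)):
            edges.setdefault(e.key, e)
    return list(edges.values())


def oracle_g1(net, effects, inputs, c_max, mode="directed"):
    """Reference multi/single-source shortest paths over the full edge set.

    Returns (existing nodes, restricted edge keys, multi-source distances,
    per-root distances) where node existence follows the creation rule:
    a non-root node exists iff its multi-source distance is below c_max.
    Per-root distances run over the graph restricted to existing nodes.
    """
    roots = sorted({net.logical_node_of(e) for e in effects})
    edges = full_priced_edges(net, mode, set(inputs) | set(roots))
    g = nx.MultiDiGraph()
    g.add_nodes_from({e.from_node for e in edges} | {e.to_node for e in edges})
    g.add_nodes_from(roots)
    for e in edges:
        g.add_edge(e.from_node, e.to_node, weight=e.cost)
    dist = nx.multi_source_dijkstra_path_length(g, roots, weight="weight")
    existing = set(roots) | {
        n for n, d in dist.items() if d < c_max - _EPS
    }
    restricted = [
        e for e in edges if e.from_node in existing and e.to_node in existing
    ]
    r = nx.MultiDiGraph()
    r.add_nodes_from(existing)
    for e in restricted:
        r.add_edge(e.from_node, e.to_node, weight=e.cost)
    pc = {
        root: nx.single_source_dijkstra_path_length(r, root, weight="weight")
        for root in roots
    }
    return existing, {e.key for e in restricted}, dist, pc


def formula_fixture(etype, a, b):
    """Construct a minimal network realising given specificity counts for one
    influence type, and return the priced edge X -> I.

    ``a``/``b`` are the two counts of the type's cost formula (for one-count
    formulas only ``b`` is used and must be >= 1; for substrate formulas the
    counts exclude the central reaction).
    """
    from metreg import Entity, Network, Reaction, Regulation

    ents, rxns, regs = [], [], []

    def met(mid):
        ents.append(Entity(id=mid, kind="metabolite", name=mid))
        return mid

    def prot(pid):
        ents.append(Entity(id=pid, kind="protein", name=pid))
        return pid

    if etype in ("reactant-of-producing", "reactant-of-consuming", "product-of-consuming"):
        x, i = met("X"), met("I")
        if etype == "reactant-of-producing":
            rxns.append(Reaction("r0", ("I",), ("X",)))
        elif etype == "reactant-of-consuming":
            rxns.append(Reaction("r0", ("X", "I"), (met("W"),)))
        else:
            rxns.append(Reaction("r0", ("X",), ("I",)))
        for k in range(a):
            rxns.append(Reaction(f"rx{k}", ("X",), (met(f"fx{k}"),)))
        for k in range(b):
            rxns.append(Reaction(f"ri{k}", ("I",), (met(f"fi{k}"),)))
    elif etype in ("enzyme-of-producing", "enzyme-of-consuming"):
        assert b >= 1
        x, i = met("X"), prot("pI")
        if etype == "enzyme-of-producing":
            rxns.append(Reaction("r0", (met("S"),), ("X",), enzymes=("pI",)))
        else:
            rxns.append(Reaction("r0", ("X",), (met("W"),), enzymes=("pI",)))
        for k in range(b - 1):
            rxns.append(
                Reaction(f"rc{k}", (met(f"c{k}a"),), (met(f"c{k}b"),), enzymes=("pI",))
            )
    elif etype == "transporter":
        assert b >= 1
        x, i = met("X"), prot("pI")
        rxns.append(
            Reaction(
                "r0", (met("S"),), ("X",), enzymes=("pI",),
                is_transport=True, transported=("X",),
            )
        )
        for k in range(b - 1):
            rxns.append(
                Reaction(
                    f"rt{k}", (met(f"t{k}a"),), (met(f"t{k}b"),), enzymes=("pI",),
                    is_transport=True, transported=(f"t{k}a",),
                )
            )
    elif etype in ("enzyme-activator", "enzyme-inhibitor", "cofactor"):
        assert b >= 1
        x, i = prot("pX"), met("I")
        rxns.append(Reaction("r0", (met("m1"),), (met("m2"),), enzymes=("pX",)))
        mode = "cofactor" if etype == "cofactor" else "enzyme-modulation"
        sign = "-" if etype == "enzyme-inhibitor" else "+"
        regs.append(Regulation("reg0", "I", "pX", mode, sign))
        for k in range(b - 1):
            enz = prot(f"pE{k}")
            rxns.append(Reaction(f"re{k}", (met(f"e{k}a"),), (met(f"e{k}b"),), enzymes=(enz,)))
            regs.append(Regulation(f"regx{k}", "I", enz, mode, sign))
    elif etype in ("transcriptional-regulator", "translational-regulator"):
        assert a >= 1 and b >= 1
        from metreg import Entity as E

        ents.append(E(id="gX", kind="gene", name="gX"))
        x, i = "gX", prot("pI")
        mode = etype.split("-")[0]
        regs.append(Regulation("reg0", "pI", "gX", mode, "+"))
        for k in range(a - 1):
            regs.append(Regulation(f"rr{k}", prot(f"tf{k}"), "gX", "transcriptional", "+"))
        for k in range(b - 1):
            ents.append(E(id=f"g{k}", kind="gene", name=f"g{k}"))
            regs.append(Regulation(f"rg{k}", "pI", f"g{k}", "transcriptional", "+"))
    elif etype == "sigma-factor":
        assert b >= 1
        from metreg import Entity as E

        ents.append(E(id="gX", kind="gene", name="gX"))
        x, i = "gX", prot("pI")
        regs.append(Regulation("reg0", "pI", "gX", "sigma-factor", "+"))
        for k in range(b - 1):
            ents.append(E(id=f"g{k}", kind="gene", name=f"g{k}"))
            regs.append(Regulation(f"rg{k}", "pI", f"g{k}", "sigma-factor", "+"))
    else:
        raise ValueError(etype)

    from metreg import Network

    net = Network.from_records(ents, rxns, regs)
    edges = [
        e
        for e in priced_influencers_of(net.logical_node_of(x), net)
        if e.to_node == net.logical_node_of(i) and e.type == etype
    ]
    assert len(edges) == 1, (etype, a, b, edges)
    return net, edges[0]


def brute_force_paths(g1, root, terminus, bound):
    """All simple root->terminus edge sequences within the cost bound,
    found by unpruned recursion over the stored G1 edges."""
    results = []

    def rec(node, cost, visited, trail):
        if node == terminus and trail:
            results.append((cost, tuple(trail)))
            return
        for edge in g1.edges_from(node):
            if edge.to_node in visited:
                continue
            rec(
                edge.to_node,
                cost + edge.cost,
                visited | {edge.to_node},
                trail + [edge.key],
            )

    rec(root, 0.0, {root}, [])
    return sorted((c, t) for c, t in results if c <= bound + _EPS)
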