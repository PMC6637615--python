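"""Influence enumeration and edge pricing.

Each edge of the influence graph records that an influencer *I* can change
the abundance or activity of an influenced entity *X*.  Edges are stored in
search direction X -> I (the graph is explored outward from the observed
effects), while the biological influence runs I -> X.

Edge costs implement a specificity-weighted scheme: most costs are
1 (or 2, for consumption-side influences, biasing the search toward
upstream/production-side explanations) plus a term proportional to how many
reactions or genes the participants touch.  Hub metabolites and global
regulators therefore price high and specific interactions price low.
Complex-component edges are flat 0.1; transcription-unit co-membership is a
free (cost 0) but dead-end link used only in undirected mode, where it
explains correlated genes.  An influencer that is itself one of the user's
input entities always prices 0.1, biasing paths toward the entities of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

from .network_model import Network

# The 14 influence-type codes (an activator/inhibitor split of the single
# enzyme-modulation pricing row, since their signs differ).
INFLUENCE_TYPES = (
    "reactant-of-producing",
    "reactant-of-consuming",
    "product-of-consuming",
    "enzyme-of-producing",
    "enzyme-of-consuming",
    "transporter",
    "enzyme-activator",
    "enzyme-inhibitor",
    "cofactor",
    "transcriptional-regulator",
    "translational-regulator",
    "sigma-factor",
    "complex-component",
    "transcription-unit",
)

#: Influence types derived from reactions (used by the display phase to
#: separate metabolic from regulatory structure).
REACTION_TYPES = frozenset(
    {
        "reactant-of-producing",
        "reactant-of-consuming",
        "product-of-consuming",
        "enzyme-of-producing",
        "enzyme-of-consuming",
        "transporter",
    }
)

SIGNS = ("+", "-", "ambiguous")

#: Default sign policy: influence direction is I -> X.  Regulation-backed
#: types take the sign of the regulation record; reversible-reaction-derived
#: edges are always forced to "ambiguous" (either parity can be supported
#: through a reversible reaction).  The table is replaceable by the caller.
DEFAULT_SIGN_POLICY: dict[str, str] = {
    "reactant-of-producing": "+",
    "reactant-of-consuming": "-",
    "product-of-consuming": "ambiguous",
    "enzyme-of-producing": "+",
    "enzyme-of-consuming": "-",
    "transporter": "+",  # import assumed
    "enzyme-activator": "+",
    "enzyme-inhibitor": "-",
    "cofactor": "+",
    "transcriptional-regulator": "regulation",
    "translational-regulator": "regulation",
    "sigma-factor": "+",
    "complex-component": "+",
    "transcription-unit": "ambiguous",
}


@dataclass(frozen=True)
class InfluenceEdge:
    """A priced influence of ``to_node`` (the influencer I) on ``from_node``
    (the influenced entity X).  ``via`` is (record id, role detail)."""

    from_node: str
    to_node: str
    type: str
    via: tuple[str, str]
    sign: str = "ambiguous"
    cost: Optional[float] = None

    @property
    def key(self) -> tuple[str, str, str, tuple[str, str]]:
        return (self.from_node, self.to_node, self.type, self.via)


def edge_sign(
    edge_type: str,
    regulation_sign: Optional[str] = None,
    reversible: bool = False,
    policy: Optional[Mapping[str, str]] = None,
) -> str:
    """Resolve the sign of an influence edge under a sign policy."""
    if edge_type not in INFLUENCE_TYPES:
        raise ValueError(f"unknown influence type {edge_type!r}")
    if reversible:
        return "ambiguous"
    policy = DEFAULT_SIGN_POLICY if policy is None else policy
    rule = policy[edge_type]
    if rule == "regulation":
        return regulation_sign if regulation_sign in ("+", "-") else "ambiguous"
    return rule


def _oriented_sides(rxn) -> list[tuple[str, tuple[str, ...], tuple[str, ...], bool]]:
    """(role tag, consumed side, produced side, from-reversible) per orientation."""
    if rxn.direction == "left-to-right":
        return [("fwd", rxn.reactants, rxn.products, False)]
    if rxn.direction == "right-to-left":
        return [("rev", rxn.products, rxn.reactants, False)]
    return [
        ("fwd", rxn.reactants, rxn.products, True),
        ("rev", rxn.products, rxn.reactants, True),
    ]


def influencers_of(
    node: str,
    net: Network,
    mode: str = "directed",
    sign_policy: Optional[Mapping[str, str]] = None,
) -> list[InfluenceEdge]:
    """Enumerate all (uncosted) influence edges out of a logical node.

    Substrate-role edges are emitted only when the node is a non-ubiquitous
    reaction substrate; for small molecules, protein-binding reactions are
    skipped.  Regulatory, modulation, cofactor and component edges apply to
    gene/protein/complex nodes.  Transcription-unit edges are emitted only in
    undirected mode, and point at the transcription-unit id itself (a
    dead-end node).
    """
    if mode not in ("directed", "undirected"):
        raise ValueError(f"unknown mode {mode!r}")
    if not net.is_entity_node(node):
        if node in net.transcription_units:
            return []  # TU nodes are dead ends
        raise KeyError(f"unknown logical node {node!r}")

    members = net.members_of(node)
    kinds = net.node_kinds(node)
    small = net.is_small_molecule(node)
    ubiquitous = net.is_ubiquitous(node)
    edges: dict[tuple, InfluenceEdge] = {}

    def add(to_node: str, etype: str, via: tuple[str, str], sign: str) -> None:
        if to_node == node:
            return
        e = InfluenceEdge(node, to_node, etype, via, sign)
        edges.setdefault(e.key, e)

    # --- substrate roles -------------------------------------------------
    if not ubiquitous:
        for rxn in net.reactions.values():
            if small and rxn.is_protein_binding:
                continue
            sub_logicals = {net.logical_node_of(s) for s in rxn.substrates()}
            if node not in sub_logicals:
                continue
            transported = node in {net.logical_node_of(t) for t in rxn.transported}
            for tag, consumed, produced, from_rev in _oriented_sides(rxn):
                cons = {net.logical_node_of(s) for s in consumed}
                prod = {net.logical_node_of(s) for s in produced}

                def substrate_targets(side: Iterable[str]) -> list[str]:
                    seen = []
                    for s in side:
                        ln = net.logical_node_of(s)
                        if ln != node and not net.is_ubiquitous(ln) and ln not in seen:
                            seen.append(ln)
                    return seen

                if node in prod:  # this orientation produces X
                    for ln in substrate_targets(consumed):
                        add(
                            ln,
                            "reactant-of-producing",
                            (rxn.id, tag),
                            edge_sign(
                                "reactant-of-producing", None, from_rev, sign_policy
                            ),
                        )
                    if not (rxn.is_transport and transported):
                        for enz in rxn.enzymes:
                            add(
                                net.logical_node_of(enz),
                                "enzyme-of-producing",
                                (rxn.id, tag),
                                edge_sign(
                                    "enzyme-of-producing", None, from_rev, sign_policy
                                ),
                            )
                if node in cons:  # this orientation consumes X
                    for ln in substrate_targets(consumed):
                        add(
                            ln,
                            "reactant-of-consuming",
                            (rxn.id, tag),
                            edge_sign(
                                "reactant-of-consuming", None, from_rev, sign_policy
                            ),
                        )
                    for ln in substrate_targets(produced):
                        add(
                            ln,
                            "product-of-consuming",
                            (rxn.id, tag),
                            edge_sign(
                                "product-of-consuming", None, from_rev, sign_policy
                            ),
                        )
                    if not (rxn.is_transport and transported):
                        for enz in rxn.enzymes:
                            add(
                                net.logical_node_of(enz),
                                "enzyme-of-consuming",
                                (rxn.id, tag),
                                edge_sign(
                                    "enzyme-of-consuming", None, from_rev, sign_policy
                                ),
                            )
            if rxn.is_transport and transported:
                for enz in rxn.enzymes:
                    add(
                        net.logical_node_of(enz),
                        "transporter",
                        (rxn.id, "transport"),
                        edge_sign(
                            "transporter",
                            None,
                            rxn.direction == "reversible",
                            sign_policy,
                        ),
                    )

    # --- gene / protein / complex roles ---------------------------------
    if kinds & {"gene", "protein", "complex", "modified-form"}:
        for reg in net.regulations.values():
            if net.logical_node_of(reg.regulatee) != node:
                continue
            regulator = net.logical_node_of(reg.regulator)
            if reg.mode == "enzyme-modulation":
                etype = "enzyme-activator" if reg.sign == "+" else "enzyme-inhibitor"
            elif reg.mode == "cofactor":
                etype = "cofactor"
            elif reg.mode == "transcriptional":
                etype = "transcriptional-regulator"
            elif reg.mode == "translational":
                etype = "translational-regulator"
            else:
                etype = "sigma-factor"
            add(
                regulator,
                etype,
                (reg.id, ""),
                edge_sign(etype, reg.sign, False, sign_policy),
            )

        # component edges only for heteromultimeric complexes (homomultimers
        # coalesce with their monomer and generate no self edge)
        ent = net.entities.get(node)
        if ent is not None and ent.kind == "complex":
            for cid, _ in ent.components:
                add(
                    net.logical_node_of(cid),
                    "complex-component",
                    (ent.id, ""),
                    edge_sign("complex-component", None, False, sign_policy),
                )

        if mode == "undirected" and "gene" in kinds:
            for tu in net.transcription_units.values():
                if node in {net.logical_node_of(g) for g in tu.genes}:
                    add(
                        tu.id,
                        "transcription-unit",
                        (tu.id, ""),
                        edge_sign("transcription-unit", None, False, sign_policy),
                    )

    return sorted(edges.values(), key=lambda e: (e.type, e.via, e.to_node))


def edge_cost(
    edge: InfluenceEdge,
    net: Network,
    input_entities: frozenset[str] | set[str] = frozenset(),
) -> float:
    """Price an influence edge.

    If the influencer is one of the input entities (condition or effect) the
    cost is the flat 0.1 override — except transcription-unit edges, which
    stay at 0 (the TU is never itself an input entity and the link is free by
    construction).  Otherwise the type's formula applies, driven by the
    specificity counts of the network.
    """
    x, i, etype = edge.from_node, edge.to_node, edge.type
    if etype == "transcription-unit":
        return 0.0
    if i in input_entities:
        return 0.1
    rxn_id = edge.via[0]
    if etype == "reactant-of-producing":
        return 1 + (
            net.substrate_reaction_count(x, rxn_id)
            + net.substrate_reaction_count(i, rxn_id)
        ) / 20
    if etype == "reactant-of-consuming":
        return 1 + (
            net.substrate_reaction_count(x, rxn_id)
            + net.substrate_reaction_count(i, rxn_id)
        ) / 10
    if etype == "product-of-consuming":
        return 2 + (
            net.substrate_reaction_count(x, rxn_id)
            + net.substrate_reaction_count(i, rxn_id)
        ) / 10
    if etype == "enzyme-of-producing":
        return 1 + net.enzyme_reaction_count(i) / 20
    if etype == "enzyme-of-consuming":
        return 2 + net.enzyme_reaction_count(i) / 20
    if etype == "transporter":
        return 1 + net.transporter_reaction_count(i) / 20
    if etype in ("enzyme-activator", "enzyme-inhibitor"):
        return 1 + net.modulated_enzyme_count(i) / 20
    if etype == "cofactor":
        return 1 + net.cofactor_enzyme_count(i) / 20
    if etype in ("transcriptional-regulator", "translational-regulator"):
        return 1 + (net.regulator_count(x) + net.regulated_gene_count(i)) / 20
    if etype == "sigma-factor":
        return 1 + net.regulated_gene_count(i) / 20
    if etype == "complex-component":
        return 0.1
    raise ValueError(f"unknown influence type {etype!r}")


def priced_influencers_of(
    node: str,
    net: Network,
    mode: str = "directed",
    input_entities: frozenset[str] | set[str] = frozenset(),
    sign_policy: Optional[Mapping[str, str]] = None,
) -> list[InfluenceEdge]:
    """Convenience: enumerate and price in one call."""
    return [
        replace(e, cost=edge_cost(e, net, input_entities))
        for e in influencers_of(node, net, mode, sign_policy)
    ]
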