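"""Synthetic metabolic + regulatory networks for testing and benchmarking.

Three generators:

* :func:`generate_network` — seed-deterministic random networks with
  controllable structure.  Metabolite participation in reactions is drawn
  from a heavy-tailed weight distribution so that hub compounds exist and
  specificity weighting is actually exercised.
* :func:`toy_network` — a small fixed network of five enzyme-catalysed
  reactions and three transcription factors, modelled on the classic
  worked example of this kind of tool (E1 converts M0 to M1; TF0 inhibits
  expression of TF1 and activates expression of E5).  The accompanying
  :func:`toy_manifest` labels each relation as part of that published
  topology or as a fixture invention.
* :func:`planted_path_network` — a network containing one ground-truth
  condition-to-effect path realised with a requested sequence of influence
  types, plus random decoy structure; used for end-to-end recovery tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .network_model import (
    Entity,
    Network,
    Reaction,
    Regulation,
    TranscriptionUnit,
)


@dataclass(frozen=True)
class SynthParams:
    n_metabolites: int = 24
    n_reactions: int = 20
    n_enzymes: int = 12
    n_tfs: int = 5
    p_reversible: float = 0.2
    p_transport: float = 0.1
    p_regulation: float = 0.25
    p_modulation: float = 0.08
    p_cofactor: float = 0.05
    n_tus: int = 3
    ubiquitous_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "p_reversible",
            "p_transport",
            "p_regulation",
            "p_modulation",
            "p_cofactor",
            "ubiquitous_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_metabolites", "n_reactions", "n_enzymes", "n_tfs", "n_tus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_reactions > 0 and self.n_metabolites < 2:
            raise ValueError("reactions require at least two metabolites")
        if self.n_tus > 0 and self.n_enzymes + self.n_tfs == 0:
            raise ValueError("transcription units require genes")


def generate_network(params: SynthParams) -> Network:
    """Generate a random valid network realising every influence type that
    has nonzero probability mass under the parameters."""
    params.validate()
    rng = random.Random(params.seed)

    entities: list[Entity] = []
    reactions: list[Reaction] = []
    regulations: list[Regulation] = []
    tus: list[TranscriptionUnit] = []

    mets = [f"m{i:03d}" for i in range(params.n_metabolites)]
    for i, mid in enumerate(mets):
        ubiq = rng.random() < params.ubiquitous_fraction
        entities.append(
            Entity(id=mid, kind="metabolite", name=mid.upper(), ubiquitous=ubiq)
        )
    # heavy-tailed participation weights: hub metabolites exist
    met_weights = [1.0 / (rank + 1) for rank in range(len(mets))]

    def pick_mets(k: int, exclude: set[str]) -> list[str]:
        pool = [(m, w) for m, w in zip(mets, met_weights) if m not in exclude]
        chosen: list[str] = []
        for _ in range(min(k, len(pool))):
            total = sum(w for _, w in pool)
            r = rng.random() * total
            acc = 0.0
            for j, (m, w) in enumerate(pool):
                acc += w
                if acc >= r:
                    chosen.append(m)
                    pool.pop(j)
                    break
        return chosen

    # enzymes: gene + protein; some homodimers, heterodimers, modified forms
    enzyme_catalysts: list[str] = []  # entity ids usable as catalysts
    enzyme_proteins: list[str] = []
    for i in range(params.n_enzymes):
        g, p = f"gE{i:02d}", f"pE{i:02d}"
        entities.append(Entity(id=g, kind="gene", name=g))
        entities.append(Entity(id=p, kind="protein", name=p, product_of=g))
        enzyme_proteins.append(p)
        catalyst = p
        if i % 4 == 1:  # homodimer, coalesces with its monomer/gene
            d = f"dE{i:02d}"
            entities.append(
                Entity(id=d, kind="complex", name=d, components=((p, 2),))
            )
            catalyst = d
        if i % 5 == 2:  # phosphorylated form: a distinct logical node
            entities.append(
                Entity(id=f"{p}_p", kind="modified-form", name=f"{p}-P", base_entity=p)
            )
        enzyme_catalysts.append(catalyst)
    # heterodimers of adjacent enzyme proteins
    for i in range(0, params.n_enzymes - 1, 7):
        h = f"hE{i:02d}"
        entities.append(
            Entity(
                id=h,
                kind="complex",
                name=h,
                components=((enzyme_proteins[i], 1), (enzyme_proteins[i + 1], 1)),
            )
        )
        enzyme_catalysts.append(h)

    tf_proteins: list[str] = []
    tf_genes: list[str] = []
    for i in range(params.n_tfs):
        g, p = f"gTF{i:02d}", f"pTF{i:02d}"
        entities.append(Entity(id=g, kind="gene", name=g))
        entities.append(Entity(id=p, kind="protein", name=p, product_of=g))
        tf_genes.append(g)
        tf_proteins.append(p)

    for i in range(params.n_reactions):
        nr = 1 + (rng.random() < 0.4)
        np_ = 1 + (rng.random() < 0.4)
        reactants = pick_mets(nr, set())
        products = pick_mets(np_, set(reactants))
        if not reactants or not products:
            continue
        direction = "reversible" if rng.random() < params.p_reversible else "left-to-right"
        enzymes = ()
        if enzyme_catalysts and rng.random() < 0.9:
            enzymes = (rng.choice(enzyme_catalysts),)
        is_transport = rng.random() < params.p_transport
        transported = (reactants[0],) if is_transport else ()
        reactions.append(
            Reaction(
                id=f"r{i:03d}",
                reactants=tuple(reactants),
                products=tuple(products),
                direction=direction,
                enzymes=enzymes,
                is_transport=is_transport,
                transported=transported,
            )
        )

    # protein-ligand binding: TF + metabolite -> active complex
    if tf_proteins and mets and params.n_reactions > 0:
        p = tf_proteins[0]
        ligand = mets[-1]
        cplx = "cplx_lig0"
        entities.append(
            Entity(id=cplx, kind="complex", name=cplx, components=((p, 1), (ligand, 1)))
        )
        reactions.append(
            Reaction(
                id="r_bind0",
                reactants=(p, ligand),
                products=(cplx,),
                direction="left-to-right",
                is_protein_binding=True,
            )
        )

    catalyzing = sorted(
        {e for r in reactions for e in r.enzymes},
    )
    all_genes = [f"gE{i:02d}" for i in range(params.n_enzymes)] + tf_genes
    regno = 0
    for p in tf_proteins:
        for g in all_genes:
            if g == f"g{p[1:]}":
                continue
            if rng.random() < params.p_regulation:
                mode = "translational" if rng.random() < 0.15 else "transcriptional"
                sign = "+" if rng.random() < 0.6 else "-"
                regulations.append(
                    Regulation(f"reg{regno:03d}", p, g, mode, sign)
                )
                regno += 1
    # one sigma factor regulating a couple of genes
    if tf_proteins and all_genes:
        sigma = tf_proteins[-1]
        for g in all_genes[:: max(1, len(all_genes) // 3)]:
            if g != f"g{sigma[1:]}":
                regulations.append(
                    Regulation(f"reg{regno:03d}", sigma, g, "sigma-factor", "+")
                )
                regno += 1
    for m in mets:
        for enz in catalyzing:
            if rng.random() < params.p_modulation:
                sign = "+" if rng.random() < 0.5 else "-"
                regulations.append(
                    Regulation(f"reg{regno:03d}", m, enz, "enzyme-modulation", sign)
                )
                regno += 1
            if rng.random() < params.p_cofactor:
                regulations.append(
                    Regulation(f"reg{regno:03d}", m, enz, "cofactor", "+")
                )
                regno += 1

    gene_pool = list(all_genes)
    for i in range(params.n_tus):
        if len(gene_pool) < 2:
            break
        size = min(len(gene_pool), 2 + (rng.random() < 0.5))
        members = [gene_pool.pop(rng.randrange(len(gene_pool))) for _ in range(size)]
        tus.append(TranscriptionUnit(f"tu{i:02d}", tuple(sorted(members))))

    return Network.from_records(entities, reactions, regulations, tus)


# ----------------------------------------------------------------------
# fixed toy fixture
# ----------------------------------------------------------------------
def toy_network() -> Network:
    """A fixed 5-reaction / 3-TF fixture.

    The published relations it preserves: E1 catalyses M0 -> M1; TF0
    inhibits expression of TF1; TF0 activates expression of E5.  All other
    structure is fixture invention (see :func:`toy_manifest`).
    """
    entities = [Entity(id=f"M{i}", kind="metabolite", name=f"M{i}") for i in range(6)]
    entities.append(Entity(id="WATER", kind="metabolite", name="water"))
    for i in range(1, 6):
        entities.append(Entity(id=f"gE{i}", kind="gene", name=f"gE{i}"))
        entities.append(
            Entity(id=f"E{i}", kind="protein", name=f"E{i}", product_of=f"gE{i}")
        )
    for i in range(3):
        entities.append(Entity(id=f"gTF{i}", kind="gene", name=f"gTF{i}"))
        entities.append(
            Entity(id=f"TF{i}", kind="protein", name=f"TF{i}", product_of=f"gTF{i}")
        )
    # homodimer of TF0: coalesces with TF0/gTF0
    entities.append(
        Entity(id="TF0_dim", kind="complex", name="TF0 dimer", components=(("TF0", 2),))
    )
    reactions = [
        Reaction("R1", ("M0",), ("M1",), enzymes=("E1",)),
        Reaction("R2", ("M1", "WATER"), ("M2",), enzymes=("E2",)),
        Reaction("R3", ("M2",), ("M3",), enzymes=("E3",)),
        Reaction("R4", ("M3",), ("M4",), enzymes=("E4",)),
        Reaction("R5", ("M5",), ("M0",), enzymes=("E5",)),
    ]
    regulations = [
        Regulation("reg1", "TF0", "gTF1", "transcriptional", "-"),
        Regulation("reg2", "TF0", "gE5", "transcriptional", "+"),
        Regulation("reg3", "TF1", "gE2", "transcriptional", "+"),
        Regulation("reg4", "TF1", "gE3", "transcriptional", "-"),
        Regulation("reg5", "TF2", "gE4", "transcriptional", "+"),
        Regulation("reg6", "M3", "E1", "enzyme-modulation", "-"),
        Regulation("reg7", "M5", "E1", "cofactor", "+"),
    ]
    tus = [TranscriptionUnit("tu1", ("gE2", "gE3"))]
    return Network.from_records(entities, reactions, regulations, tus)


def toy_manifest() -> dict:
    """Provenance of each toy relation ('published' topology vs 'invented'
    fixture completion) and the record counts of the fixture."""
    net = toy_network()
    return {
        "relations": {
            "R1: E1 catalyses M0 -> M1": "published",
            "reg1: TF0 inhibits expression of TF1": "published",
            "reg2: TF0 activates expression of E5": "published",
            "R2: E2 catalyses M1 + water -> M2": "invented",
            "R3: E3 catalyses M2 -> M3": "invented",
            "R4: E4 catalyses M3 -> M4": "invented",
            "R5: E5 catalyses M5 -> M0": "invented",
            "reg3: TF1 activates E2": "invented",
            "reg4: TF1 inhibits E3": "invented",
            "reg5: TF2 activates E4": "invented",
            "reg6: M3 inhibits enzyme E1": "invented",
            "reg7: M5 cofactor of enzyme E1": "invented",
            "tu1: gE2/gE3 co-transcribed": "invented",
            "TF0_dim: homodimer of TF0": "invented",
        },
        "counts": {
            "entities": len(net.entities),
            "reactions": len(net.reactions),
            "regulations": len(net.regulations),
            "transcription_units": len(net.transcription_units),
        },
    }


# ----------------------------------------------------------------------
# planted-path harness
# ----------------------------------------------------------------------
class PlantedSpecError(ValueError):
    pass


# what the influenced entity X of each edge type may be
_REQUIRED_X = {
    "reactant-of-producing": {"metabolite", "protein", "complex"},
    "reactant-of-consuming": {"metabolite", "protein", "complex"},
    "product-of-consuming": {"metabolite", "protein", "complex"},
    "enzyme-of-producing": {"metabolite", "protein", "complex"},
    "enzyme-of-consuming": {"metabolite", "protein", "complex"},
    "transporter": {"metabolite", "protein", "complex"},
    "enzyme-activator": {"protein"},
    "enzyme-inhibitor": {"protein"},
    "cofactor": {"protein"},
    "transcriptional-regulator": {"protein"},
    "translational-regulator": {"protein"},
    "sigma-factor": {"protein"},
    "complex-component": {"complex"},
    "transcription-unit": {"protein"},
}
# what the influencer I of each edge type may be (preference order)
_ALLOWED_I = {
    "reactant-of-producing": ("metabolite", "protein", "complex"),
    "reactant-of-consuming": ("metabolite", "protein", "complex"),
    "product-of-consuming": ("metabolite", "protein", "complex"),
    "enzyme-of-producing": ("protein",),
    "enzyme-of-consuming": ("protein",),
    "transporter": ("protein",),
    "enzyme-activator": ("metabolite", "protein", "complex"),
    "enzyme-inhibitor": ("metabolite", "protein", "complex"),
    "cofactor": ("metabolite", "protein"),
    "transcriptional-regulator": ("protein", "complex"),
    "translational-regulator": ("protein",),
    "sigma-factor": ("protein",),
    "complex-component": ("component",),  # resolved from the complex itself
    "transcription-unit": ("tu",),
}

_EDGE_SIGNS = {
    "enzyme-inhibitor": "-",
    "transcriptional-regulator": "+",
    "translational-regulator": "+",
}


@dataclass
class _Builder:
    entities: list[Entity] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    regulations: list[Regulation] = field(default_factory=list)
    tus: list[TranscriptionUnit] = field(default_factory=list)
    n: int = 0

    def uid(self, prefix: str) -> str:
        self.n += 1
        return f"{prefix}{self.n:03d}"


@dataclass
class _PathNode:
    kind: str  # metabolite | protein | complex | tu
    logical: str  # logical node id
    substrate: str  # entity id usable as a reaction substrate
    gene: Optional[str] = None
    component: Optional[str] = None  # for complexes: a designated component
    component_kind: str = "protein"


def _make_node(b: _Builder, kind: str, component_kind: str = "protein") -> _PathNode:
    if kind == "metabolite":
        mid = b.uid("pm")
        b.entities.append(Entity(id=mid, kind="metabolite", name=mid))
        return _PathNode("metabolite", mid, mid)
    if kind == "protein":
        g, p = b.uid("pg"), b.uid("pp")
        b.entities.append(Entity(id=g, kind="gene", name=g))
        b.entities.append(Entity(id=p, kind="protein", name=p, product_of=g))
        return _PathNode("protein", g, p, gene=g)
    if kind == "complex":
        if component_kind == "metabolite":
            comp = b.uid("pm")
            b.entities.append(Entity(id=comp, kind="metabolite", name=comp))
        else:
            gg, comp = b.uid("pg"), b.uid("pp")
            b.entities.append(Entity(id=gg, kind="gene", name=gg))
            b.entities.append(Entity(id=comp, kind="protein", name=comp, product_of=gg))
        g2, p2 = b.uid("pg"), b.uid("pp")
        b.entities.append(Entity(id=g2, kind="gene", name=g2))
        b.entities.append(Entity(id=p2, kind="protein", name=p2, product_of=g2))
        cid = b.uid("pc")
        b.entities.append(
            Entity(id=cid, kind="complex", name=cid, components=((comp, 1), (p2, 1)))
        )
        return _PathNode(
            "complex", cid, cid, component=comp, component_kind=component_kind
        )
    raise PlantedSpecError(f"cannot create a path node of kind {kind!r}")


def _filler_met(b: _Builder) -> str:
    """Ubiquitous helper metabolite: completes a reaction without licensing
    substrate edges, so it cannot open bypass routes around the path."""
    mid = b.uid("pm")
    b.entities.append(Entity(id=mid, kind="metabolite", name=mid, ubiquitous=True))
    return mid


def _ensure_catalyst(b: _Builder, node: _PathNode) -> None:
    if any(node.substrate in r.enzymes for r in b.reactions):
        return
    a, c = _filler_met(b), _filler_met(b)
    b.reactions.append(
        Reaction(b.uid("pr"), (a,), (c,), enzymes=(node.substrate,))
    )


def planted_path_network(
    path_spec: Sequence[str],
    decoys: int = 20,
    seed: int = 0,
) -> tuple[Network, tuple[tuple[str, str, str], ...]]:
    """Build a network with one ground-truth effect -> condition path.

    ``path_spec`` lists the influence types along the path, ordered from the
    effect entity outward; the last influencer is the condition.  Returns
    the network and the expected path skeleton as (from, to, type) triples
    over logical node ids.  A transcription-unit step may only appear last
    (the TU node is a dead end).
    """
    if not path_spec:
        raise PlantedSpecError("path_spec must be non-empty")
    for t in path_spec:
        if t not in _REQUIRED_X:
            raise PlantedSpecError(f"unknown influence type {t!r}")
    if "transcription-unit" in path_spec[:-1]:
        raise PlantedSpecError("transcription-unit edges are dead ends: last only")

    b = _Builder()
    rng = random.Random(seed)

    # choose node kinds along the chain
    first_kind = sorted(_REQUIRED_X[path_spec[0]])[0]  # deterministic preference
    if "metabolite" in _REQUIRED_X[path_spec[0]]:
        first_kind = "metabolite"
    kinds = [first_kind]
    for i, t in enumerate(path_spec):
        opts = _ALLOWED_I[t]
        if opts == ("component",):
            kinds.append("component")
            continue
        if opts == ("tu",):
            kinds.append("tu")
            continue
        if i + 1 < len(path_spec):
            nxt = _REQUIRED_X[path_spec[i + 1]]
            usable = [k for k in opts if k in nxt]
            if not usable:
                raise PlantedSpecError(
                    f"no influencer kind links {t!r} to {path_spec[i + 1]!r}"
                )
            kinds.append(usable[0])
        else:
            kinds.append(opts[0])

    # materialise nodes (complexes need to know their component's kind)
    nodes: list[_PathNode] = []
    for i, k in enumerate(kinds):
        if k == "component":
            prev = nodes[-1]
            if prev.kind != "complex":
                raise PlantedSpecError("complex-component requires a complex X")
            if prev.component_kind == "metabolite":
                comp_node = _PathNode("metabolite", prev.component, prev.component)
            else:
                prot = next(e for e in b.entities if e.id == prev.component)
                comp_node = _PathNode(
                    "protein",
                    prot.product_of or prot.id,
                    prot.id,
                    gene=prot.product_of,
                )
            nodes.append(comp_node)
        elif k == "tu":
            nodes.append(_PathNode("tu", "", ""))  # filled when realised
        elif k == "complex":
            nxt_kind = "protein"
            if i < len(kinds) - 1 and kinds[i + 1] == "component" and i + 1 < len(
                path_spec
            ):
                want = _REQUIRED_X[path_spec[i + 1]]
                nxt_kind = "metabolite" if want == {"metabolite"} else "protein"
            nodes.append(_make_node(b, "complex", component_kind=nxt_kind))
        else:
            nodes.append(_make_node(b, k))

    # realise each edge
    expected: list[tuple[str, str, str]] = []
    for i, t in enumerate(path_spec):
        x, inf = nodes[i], nodes[i + 1]
        if t == "reactant-of-producing":
            b.reactions.append(
                Reaction(b.uid("pr"), (inf.substrate,), (x.substrate,))
            )
        elif t == "reactant-of-consuming":
            waste = _filler_met(b)
            b.reactions.append(
                Reaction(b.uid("pr"), (x.substrate, inf.substrate), (waste,))
            )
        elif t == "product-of-consuming":
            b.reactions.append(
                Reaction(b.uid("pr"), (x.substrate,), (inf.substrate,))
            )
        elif t == "enzyme-of-producing":
            src = _filler_met(b)
            b.reactions.append(
                Reaction(b.uid("pr"), (src,), (x.substrate,), enzymes=(inf.substrate,))
            )
        elif t == "enzyme-of-consuming":
            waste = _filler_met(b)
            b.reactions.append(
                Reaction(b.uid("pr"), (x.substrate,), (waste,), enzymes=(inf.substrate,))
            )
        elif t == "transporter":
            ext = _filler_met(b)
            b.reactions.append(
                Reaction(
                    b.uid("pr"),
                    (ext,),
                    (x.substrate,),
                    enzymes=(inf.substrate,),
                    is_transport=True,
                    transported=(x.substrate,),
                )
            )
        elif t in ("enzyme-activator", "enzyme-inhibitor", "cofactor"):
            _ensure_catalyst(b, x)
            mode = "cofactor" if t == "cofactor" else "enzyme-modulation"
            sign = "+" if t != "enzyme-inhibitor" else "-"
            b.regulations.append(
                Regulation(b.uid("prg"), inf.substrate, x.substrate, mode, sign)
            )
        elif t in ("transcriptional-regulator", "translational-regulator", "sigma-factor"):
            mode = {
                "transcriptional-regulator": "transcriptional",
                "translational-regulator": "translational",
                "sigma-factor": "sigma-factor",
            }[t]
            target = x.gene or x.substrate
            b.regulations.append(
                Regulation(b.uid("prg"), inf.substrate, target, mode, "+")
            )
        elif t == "complex-component":
            pass  # realised by the complex's component list
        elif t == "transcription-unit":
            other_g = b.uid("pg")
            b.entities.append(Entity(id=other_g, kind="gene", name=other_g))
            tu_id = b.uid("ptu")
            b.tus.append(TranscriptionUnit(tu_id, (x.gene or x.substrate, other_g)))
            inf.logical = tu_id
        expected.append((x.logical, inf.logical, t))

    # decoy structure: a random cluster plus dead-end influencers attached to
    # path nodes (no decoy offers an alternative route to the condition)
    decoy_mets = []
    for i in range(decoys):
        mid = f"dm{i:03d}"
        b.entities.append(Entity(id=mid, kind="metabolite", name=mid))
        decoy_mets.append(mid)
    for i in range(decoys // 2):
        if len(decoy_mets) < 2:
            break
        a, c = rng.sample(decoy_mets, 2)
        b.reactions.append(Reaction(f"dr{i:03d}", (a,), (c,)))
    path_mets = [n for n in nodes[:-1] if n.kind == "metabolite"]
    for i in range(min(decoys // 4, len(decoy_mets))):
        if not path_mets:
            break
        target = rng.choice(path_mets)
        b.reactions.append(
            Reaction(f"da{i:03d}", (decoy_mets[i],), (target.substrate,))
        )
    if decoys > 0:
        g, p = "dgTF", "dpTF"
        b.entities.append(Entity(id=g, kind="gene", name=g))
        b.entities.append(Entity(id=p, kind="protein", name=p, product_of=g))
        for i, node in enumerate(n for n in nodes[:-1] if n.gene):
            b.regulations.append(
                Regulation(f"dreg{i:03d}", p, node.gene, "transcriptional", "+")
            )

    net = Network.from_records(b.entities, b.reactions, b.regulations, b.tus)
    return net, tuple(expected)
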