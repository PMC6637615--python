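"""Data model for a combined metabolic + regulatory network.

The network is a self-contained JSON document with five arrays (entities,
reactions, regulations, transcription units, meta).  Entities cover genes,
proteins, protein complexes, chemically modified forms and metabolites.
Reactions carry direction, catalysts and transport/protein-binding flags;
regulations cover transcriptional, translational, sigma-factor,
substrate-level enzyme modulation and cofactor relationships; transcription
units group co-transcribed genes.

Two ideas from this module drive everything downstream:

* **Logical-entity coalescing** — a gene, its product, and any homomultimeric
  complex of the product are treated as a single logical node (canonical id:
  the gene's).  Chemically modified forms (e.g. a phosphoprotein) and
  heteromultimeric complexes remain distinct nodes.
* **Specificity counts** — the number of reactions a metabolite participates
  in, the number of genes a regulator controls, etc.  These feed the edge-cost
  formulas that bias path search away from hub metabolites and global
  regulators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

SCHEMA_VERSION = "1"

ENTITY_KINDS = ("gene", "protein", "complex", "metabolite", "modified-form")
REACTION_DIRECTIONS = ("left-to-right", "right-to-left", "reversible")
REGULATION_MODES = (
    "transcriptional",
    "translational",
    "sigma-factor",
    "enzyme-modulation",
    "cofactor",
)

#: Compound names treated as ubiquitous (excluded from substrate edges) when
#: an entity carries no explicit ``ubiquitous`` flag.  User data overrides
#: this list simply by setting the flag.
DEFAULT_UBIQUITOUS_NAMES = frozenset(
    n.lower()
    for n in (
        "water",
        "H2O",
        "ATP",
        "ADP",
        "AMP",
        "phosphate",
        "diphosphate",
        "H+",
        "NAD",
        "NADH",
        "NADP",
        "NADPH",
        "CO2",
        "O2",
    )
)


class NetworkError(Exception):
    """Base class for network file / validation problems."""


class ParseError(NetworkError):
    """Raised when a network file cannot be parsed; carries record context."""


class DuplicateIdError(NetworkError):
    pass


class DanglingReferenceError(NetworkError):
    pass


class ValidationError(NetworkError):
    pass


@dataclass(frozen=True)
class Entity:
    id: str
    kind: str
    name: str = ""
    #: (component entity id, copy count) pairs; non-empty iff kind == complex.
    components: tuple[tuple[str, int], ...] = ()
    #: Unmodified parent for modified forms; present iff kind == modified-form.
    base_entity: Optional[str] = None
    #: For a protein: the gene it is the product of (drives coalescing).
    product_of: Optional[str] = None
    ubiquitous: Optional[bool] = None

    def display_name(self) -> str:
        return self.name or self.id


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    direction: str = "left-to-right"
    enzymes: tuple[str, ...] = ()
    is_transport: bool = False
    transported: tuple[str, ...] = ()
    is_protein_binding: bool = False

    def substrates(self) -> tuple[str, ...]:
        return self.reactants + self.products


@dataclass(frozen=True)
class Regulation:
    id: str
    regulator: str
    regulatee: str
    mode: str
    sign: str = "+"


@dataclass(frozen=True)
class TranscriptionUnit:
    id: str
    genes: tuple[str, ...]


@dataclass
class Network:
    """A validated metabolic + regulatory network.

    Construction through :func:`load_network` or the ``Network(...)``
    constructor followed by :meth:`validate` resolves the default ubiquitous
    list and builds the logical-node index used by all queries.
    """

    entities: dict[str, Entity] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    regulations: dict[str, Regulation] = field(default_factory=dict)
    transcription_units: dict[str, TranscriptionUnit] = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    # Lazily built caches; never compared for equality.
    _logical: dict[str, str] = field(default_factory=dict, compare=False, repr=False)
    _members: dict[str, tuple[str, ...]] = field(
        default_factory=dict, compare=False, repr=False
    )

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        entities: Iterable[Entity] = (),
        reactions: Iterable[Reaction] = (),
        regulations: Iterable[Regulation] = (),
        transcription_units: Iterable[TranscriptionUnit] = (),
        schema_version: str = SCHEMA_VERSION,
    ) -> "Network":
        net = cls(schema_version=schema_version)
        for ent in entities:
            if ent.id in net.entities:
                raise DuplicateIdError(f"duplicate entity id {ent.id!r}")
            net.entities[ent.id] = ent
        for rxn in reactions:
            if rxn.id in net.reactions:
                raise DuplicateIdError(f"duplicate reaction id {rxn.id!r}")
            net.reactions[rxn.id] = rxn
        for reg in regulations:
            if reg.id in net.regulations:
                raise DuplicateIdError(f"duplicate regulation id {reg.id!r}")
            net.regulations[reg.id] = reg
        for tu in transcription_units:
            if tu.id in net.transcription_units:
                raise DuplicateIdError(f"duplicate transcription unit id {tu.id!r}")
            net.transcription_units[tu.id] = tu
        net.validate()
        return net

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.entities == other.entities
            and self.reactions == other.reactions
            and self.regulations == other.regulations
            and self.transcription_units == other.transcription_units
            and self.schema_version == other.schema_version
        )

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check all invariants; raises a NetworkError subclass on failure."""
        ents = self.entities

        def require_entity(eid: str, ctx: str) -> Entity:
            ent = ents.get(eid)
            if ent is None:
                raise DanglingReferenceError(f"{ctx} references unknown entity {eid!r}")
            return ent

        for ent in ents.values():
            if ent.kind not in ENTITY_KINDS:
                raise ValidationError(f"entity {ent.id!r}: unknown kind {ent.kind!r}")
            if (ent.kind == "complex") != bool(ent.components):
                raise ValidationError(
                    f"entity {ent.id!r}: components must be non-empty iff kind=complex"
                )
            if (ent.kind == "modified-form") != (ent.base_entity is not None):
                raise ValidationError(
                    f"entity {ent.id!r}: base_entity present iff kind=modified-form"
                )
            for cid, count in ent.components:
                require_entity(cid, f"complex {ent.id!r}")
                if count < 1:
                    raise ValidationError(
                        f"complex {ent.id!r}: copy count for {cid!r} must be >= 1"
                    )
            if ent.base_entity is not None:
                require_entity(ent.base_entity, f"modified form {ent.id!r}")
            if ent.product_of is not None:
                gene = require_entity(ent.product_of, f"product link of {ent.id!r}")
                if gene.kind != "gene":
                    raise ValidationError(
                        f"entity {ent.id!r}: product_of target {gene.id!r} is not a gene"
                    )

        self._check_composition_acyclic()

        for rxn in self.reactions.values():
            if rxn.direction not in REACTION_DIRECTIONS:
                raise ValidationError(
                    f"reaction {rxn.id!r}: unknown direction {rxn.direction!r}"
                )
            if not rxn.reactants or not rxn.products:
                raise ValidationError(
                    f"reaction {rxn.id!r}: needs at least one substrate on each side"
                )
            if set(rxn.reactants) & set(rxn.products):
                raise ValidationError(
                    f"reaction {rxn.id!r}: reactants and products must be disjoint"
                )
            for eid in rxn.substrates() + rxn.enzymes:
                require_entity(eid, f"reaction {rxn.id!r}")
            if rxn.transported and not rxn.is_transport:
                raise ValidationError(
                    f"reaction {rxn.id!r}: transported species on a non-transport reaction"
                )
            extra = set(rxn.transported) - set(rxn.substrates())
            if extra:
                raise ValidationError(
                    f"reaction {rxn.id!r}: transported species {sorted(extra)} "
                    "are not substrates"
                )

        catalyst_logicals = {
            self.logical_node_of(e) for r in self.reactions.values() for e in r.enzymes
        }
        for reg in self.regulations.values():
            if reg.mode not in REGULATION_MODES:
                raise ValidationError(
                    f"regulation {reg.id!r}: unknown mode {reg.mode!r}"
                )
            if reg.sign not in ("+", "-"):
                raise ValidationError(f"regulation {reg.id!r}: sign must be + or -")
            if reg.mode in ("cofactor", "sigma-factor") and reg.sign != "+":
                raise ValidationError(
                    f"regulation {reg.id!r}: {reg.mode} regulations are fixed to sign +"
                )
            require_entity(reg.regulator, f"regulation {reg.id!r}")
            require_entity(reg.regulatee, f"regulation {reg.id!r}")
            if reg.mode in ("enzyme-modulation", "cofactor"):
                if self.logical_node_of(reg.regulatee) not in catalyst_logicals:
                    raise ValidationError(
                        f"regulation {reg.id!r}: regulatee {reg.regulatee!r} "
                        "must catalyze at least one reaction"
                    )

        for tu in self.transcription_units.values():
            if not tu.genes:
                raise ValidationError(f"transcription unit {tu.id!r}: empty gene list")
            if tu.id in ents:
                raise ValidationError(
                    f"transcription unit id {tu.id!r} collides with an entity id"
                )
            for gid in tu.genes:
                gene = require_entity(gid, f"transcription unit {tu.id!r}")
                if gene.kind != "gene":
                    raise ValidationError(
                        f"transcription unit {tu.id!r}: member {gid!r} is not a gene"
                    )

        self._resolve_ubiquitous()
        self._logical.clear()
        self._members.clear()

    def _check_composition_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(eid: str, trail: tuple[str, ...]) -> None:
            if state.get(eid) == 1:
                return
            if state.get(eid) == 0:
                raise ValidationError(
                    f"cycle in composition relation: {' -> '.join(trail + (eid,))}"
                )
            state[eid] = 0
            ent = self.entities.get(eid)
            if ent is not None:
                for cid, _ in ent.components:
                    visit(cid, trail + (eid,))
                if ent.base_entity is not None:
                    visit(ent.base_entity, trail + (eid,))
            state[eid] = 1

        for eid in self.entities:
            visit(eid, ())

    def _resolve_ubiquitous(self) -> None:
        for eid, ent in list(self.entities.items()):
            if ent.ubiquitous is None:
                flag = (
                    ent.kind == "metabolite"
                    and ent.display_name().lower() in DEFAULT_UBIQUITOUS_NAMES
                )
                self.entities[eid] = replace(ent, ubiquitous=flag)

    # ------------------------------------------------------------------
    # logical-entity coalescing
    # ------------------------------------------------------------------
    def logical_node_of(self, entity_id: str) -> str:
        """Canonical logical-node id for an entity.

        A gene, its product and homomultimers of the product share one id
        (the gene's; the monomer's when no gene link exists).  Modified forms
        and heteromultimers keep their own ids.
        """
        cached = self._logical.get(entity_id)
        if cached is not None:
            return cached
        ent = self.entities.get(entity_id)
        if ent is None:
            raise DanglingReferenceError(f"unknown entity {entity_id!r}")
        if ent.kind in ("gene", "metabolite", "modified-form"):
            result = ent.id
        elif ent.kind == "protein":
            result = ent.product_of if ent.product_of is not None else ent.id
        elif ent.kind == "complex":
            distinct = {cid for cid, _ in ent.components}
            if len(distinct) == 1:  # homomultimer: coalesce with its monomer
                result = self.logical_node_of(next(iter(distinct)))
            else:
                result = ent.id
        else:  # pragma: no cover - kinds validated earlier
            result = ent.id
        self._logical[entity_id] = result
        return result

    def members_of(self, logical_id: str) -> tuple[str, ...]:
        """All entity ids coalescing to a logical node (sorted)."""
        if not self._members:
            groups: dict[str, list[str]] = {}
            for eid in self.entities:
                groups.setdefault(self.logical_node_of(eid), []).append(eid)
            self._members = {k: tuple(sorted(v)) for k, v in groups.items()}
        return self._members.get(logical_id, ())

    def is_entity_node(self, logical_id: str) -> bool:
        """True for logical nodes backed by entities (false for TU nodes)."""
        return bool(self.members_of(logical_id))

    def node_kinds(self, logical_id: str) -> frozenset[str]:
        return frozenset(
            self.entities[eid].kind for eid in self.members_of(logical_id)
        )

    def is_small_molecule(self, logical_id: str) -> bool:
        kinds = self.node_kinds(logical_id)
        return bool(kinds) and kinds <= {"metabolite"}

    def is_ubiquitous(self, logical_id: str) -> bool:
        return any(
            self.entities[eid].ubiquitous for eid in self.members_of(logical_id)
        )

    def _logical_set(self, ids: Sequence[str]) -> set[str]:
        return {self.logical_node_of(e) for e in ids}

    # ------------------------------------------------------------------
    # specificity counts (Table of influence-type cost inputs)
    # ------------------------------------------------------------------
    def substrate_reaction_count(
        self, entity_id: str, excluding: Optional[str] = None
    ) -> int:
        """Number of *other* reactions in which the entity is a substrate.

        Ubiquitous compounds return 0 by convention (they never generate
        substrate edges).  For small molecules, protein-binding reactions are
        not counted: ligand binding changes the protein, not the pool of the
        small molecule.
        """
        node = self.logical_node_of(entity_id)
        if self.is_ubiquitous(node):
            return 0
        small = self.is_small_molecule(node)
        count = 0
        for rxn in self.reactions.values():
            if rxn.id == excluding:
                continue
            if small and rxn.is_protein_binding:
                continue
            if node in self._logical_set(rxn.substrates()):
                count += 1
        return count

    def enzyme_reaction_count(self, entity_id: str) -> int:
        node = self.logical_node_of(entity_id)
        return sum(
            1
            for rxn in self.reactions.values()
            if node in self._logical_set(rxn.enzymes)
        )

    def transporter_reaction_count(self, entity_id: str) -> int:
        node = self.logical_node_of(entity_id)
        return sum(
            1
            for rxn in self.reactions.values()
            if rxn.is_transport and node in self._logical_set(rxn.enzymes)
        )

    def modulated_enzyme_count(self, entity_id: str) -> int:
        node = self.logical_node_of(entity_id)
        return len(
            {
                self.logical_node_of(reg.regulatee)
                for reg in self.regulations.values()
                if reg.mode == "enzyme-modulation"
                and self.logical_node_of(reg.regulator) == node
            }
        )

    def cofactor_enzyme_count(self, entity_id: str) -> int:
        node = self.logical_node_of(entity_id)
        return len(
            {
                self.logical_node_of(reg.regulatee)
                for reg in self.regulations.values()
                if reg.mode == "cofactor"
                and self.logical_node_of(reg.regulator) == node
            }
        )

    def regulated_gene_count(self, entity_id: str) -> int:
        """Distinct logical targets of gene-expression regulation by the entity
        (transcriptional, translational and sigma-factor records)."""
        node = self.logical_node_of(entity_id)
        return len(
            {
                self.logical_node_of(reg.regulatee)
                for reg in self.regulations.values()
                if reg.mode in ("transcriptional", "translational", "sigma-factor")
                and self.logical_node_of(reg.regulator) == node
            }
        )

    def regulator_count(self, entity_id: str) -> int:
        """Distinct transcriptional + translational regulators of the entity."""
        node = self.logical_node_of(entity_id)
        return len(
            {
                self.logical_node_of(reg.regulator)
                for reg in self.regulations.values()
                if reg.mode in ("transcriptional", "translational")
                and self.logical_node_of(reg.regulatee) == node
            }
        )


# ----------------------------------------------------------------------
# JSON reader / writer
# ----------------------------------------------------------------------
def _record_error(category: str, index: int, record: object, msg: str) -> ParseError:
    return ParseError(f"{category}[{index}]: {msg} (record: {record!r})")


def _str_list(value: object, category: str, index: int, key: str) -> tuple[str, ...]:
    if value is None:
        return ()
    if not isinstance(value, list) or not all(isinstance(v, str) for v in value):
        raise _record_error(category, index, value, f"{key} must be a list of strings")
    return tuple(value)


def load_network(path: str | Path) -> Network:
    """Read and validate a network JSON document."""
    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top-level JSON value must be an object")
    meta = doc.get("meta", {})
    version = str(meta.get("schema_version", SCHEMA_VERSION))

    entities = []
    for i, rec in enumerate(doc.get("entities", [])):
        if not isinstance(rec, dict) or "id" not in rec or "kind" not in rec:
            raise _record_error("entities", i, rec, "missing id/kind")
        comps_raw = rec.get("components", [])
        comps: list[tuple[str, int]] = []
        for c in comps_raw:
            if (
                not isinstance(c, (list, tuple))
                or len(c) != 2
                or not isinstance(c[0], str)
            ):
                raise _record_error(
                    "entities", i, rec, "components must be [id, copy-count] pairs"
                )
            comps.append((c[0], int(c[1])))
        entities.append(
            Entity(
                id=str(rec["id"]),
                kind=str(rec["kind"]),
                name=str(rec.get("name", "")),
                components=tuple(comps),
                base_entity=rec.get("base_entity"),
                product_of=rec.get("product_of"),
                ubiquitous=rec.get("ubiquitous"),
            )
        )

    reactions = []
    for i, rec in enumerate(doc.get("reactions", [])):
        if not isinstance(rec, dict) or "id" not in rec:
            raise _record_error("reactions", i, rec, "missing id")
        reactions.append(
            Reaction(
                id=str(rec["id"]),
                reactants=_str_list(rec.get("reactants"), "reactions", i, "reactants"),
                products=_str_list(rec.get("products"), "reactions", i, "products"),
                direction=str(rec.get("direction", "left-to-right")),
                enzymes=_str_list(rec.get("enzymes"), "reactions", i, "enzymes"),
                is_transport=bool(rec.get("is_transport", False)),
                transported=_str_list(
                    rec.get("transported"), "reactions", i, "transported"
                ),
                is_protein_binding=bool(rec.get("is_protein_binding", False)),
            )
        )

    regulations = []
    for i, rec in enumerate(doc.get("regulations", [])):
        if not isinstance(rec, dict) or not {"id", "regulator", "regulatee", "mode"} <= set(
            rec
        ):
            raise _record_error(
                "regulations", i, rec, "missing id/regulator/regulatee/mode"
            )
        regulations.append(
            Regulation(
                id=str(rec["id"]),
                regulator=str(rec["regulator"]),
                regulatee=str(rec["regulatee"]),
                mode=str(rec["mode"]),
                sign=str(rec.get("sign", "+")),
            )
        )

    tus = []
    for i, rec in enumerate(doc.get("transcription_units", [])):
        if not isinstance(rec, dict) or "id" not in rec:
            raise _record_error("transcription_units", i, rec, "missing id")
        tus.append(
            TranscriptionUnit(
                id=str(rec["id"]),
                genes=_str_list(rec.get("genes"), "transcription_units", i, "genes"),
            )
        )

    return Network.from_records(entities, reactions, regulations, tus, version)


def network_to_dict(net: Network) -> dict:
    """Plain-dict form of a network with fixed key ordering (for JSON dumps)."""
    ents = []
    for ent in sorted(net.entities.values(), key=lambda e: e.id):
        rec: dict = {"id": ent.id, "kind": ent.kind, "name": ent.name}
        if ent.components:
            rec["components"] = [[cid, n] for cid, n in ent.components]
        if ent.base_entity is not None:
            rec["base_entity"] = ent.base_entity
        if ent.product_of is not None:
            rec["product_of"] = ent.product_of
        rec["ubiquitous"] = bool(ent.ubiquitous)
        ents.append(rec)
    rxns = []
    for rxn in sorted(net.reactions.values(), key=lambda r: r.id):
        rec = {
            "id": rxn.id,
            "reactants": list(rxn.reactants),
            "products": list(rxn.products),
            "direction": rxn.direction,
            "enzymes": list(rxn.enzymes),
            "is_transport": rxn.is_transport,
        }
        if rxn.transported:
            rec["transported"] = list(rxn.transported)
        rec["is_protein_binding"] = rxn.is_protein_binding
        rxns.append(rec)
    regs = [
        {
            "id": reg.id,
            "regulator": reg.regulator,
            "regulatee": reg.regulatee,
            "mode": reg.mode,
            "sign": reg.sign,
        }
        for reg in sorted(net.regulations.values(), key=lambda r: r.id)
    ]
    tus = [
        {"id": tu.id, "genes": list(tu.genes)}
        for tu in sorted(net.transcription_units.values(), key=lambda t: t.id)
    ]
    return {
        "meta": {"schema_version": net.schema_version},
        "entities": ents,
        "reactions": rxns,
        "regulations": regs,
        "transcription_units": tus,
    }


def write_network(net: Network, path: str | Path) -> None:
    """Write a network as deterministic (byte-stable) JSON."""
    path = Path(path)
    text = json.dumps(network_to_dict(net), indent=1, ensure_ascii=False)
    path.write_text(text + "\n", encoding="utf-8")


def write_tsv_dumps(net: Network, out_dir: str | Path) -> list[Path]:
    """One TSV file per record type (UTF-8, header row), for inspection."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def dump(name: str, header: Sequence[str], rows: Iterable[Sequence[object]]):
        p = out / f"{name}.tsv"
        with p.open("w", encoding="utf-8") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(v) for v in row) + "\n")
        written.append(p)

    dump(
        "entities",
        ["id", "kind", "name", "components", "base_entity", "product_of", "ubiquitous"],
        (
            [
                e.id,
                e.kind,
                e.name,
                ";".join(f"{c}x{n}" for c, n in e.components),
                e.base_entity or "",
                e.product_of or "",
                int(bool(e.ubiquitous)),
            ]
            for e in sorted(net.entities.values(), key=lambda e: e.id)
        ),
    )
    dump(
        "reactions",
        [
            "id",
            "reactants",
            "products",
            "direction",
            "enzymes",
            "is_transport",
            "transported",
            "is_protein_binding",
        ],
        (
            [
                r.id,
                ";".join(r.reactants),
                ";".join(r.products),
                r.direction,
                ";".join(r.enzymes),
                int(r.is_transport),
                ";".join(r.transported),
                int(r.is_protein_binding),
            ]
            for r in sorted(net.reactions.values(), key=lambda r: r.id)
        ),
    )
    dump(
        "regulations",
        ["id", "regulator", "regulatee", "mode", "sign"],
        (
            [g.id, g.regulator, g.regulatee, g.mode, g.sign]
            for g in sorted(net.regulations.values(), key=lambda g: g.id)
        ),
    )
    dump(
        "transcription_units",
        ["id", "genes"],
        (
            [t.id, ";".join(t.genes)]
            for t in sorted(net.transcription_units.values(), key=lambda t: t.id)
        ),
    )
    return written
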