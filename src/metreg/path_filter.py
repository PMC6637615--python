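"""Phase 2: path enumeration, parity filtering and influencer scoring.

Directed mode: for every (effect root, condition) pair present in G1,
enumerate all simple paths whose total cost stays within an offset of the
minimum path cost for that pair.  When a pair yields too many paths, the
paths are first restricted to those whose parity is consistent with the
observed directions of change (when supplied), then the offset is halved
until the count fits the budget.  The surviving paths define the filtered
graph G2.

Undirected mode: every G1 node with paths to two or more targets is an
*influencer*, scored by the sum of its minimum path costs to the targets it
reaches plus a penalty of 1.5 x c_max for every target it misses (lower
score = greater influence).  A greedy pass over the ascending ranking builds
a covering set, which is then posited as the condition set, reducing the
problem to directed mode.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from difflib import get_close_matches
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .metreg_build import MetRegGraph
from .influence_edges import InfluenceEdge
from .network_model import Network

DEFAULT_OFFSET = 2.0
DEFAULT_MAX_PATHS = 25
PENALTY_MULTIPLIER = 1.5
_EPS = 1e-9


@dataclass(frozen=True)
class TargetSpec:
    entity: str  # logical node id
    role: str  # "condition" | "effect"
    direction: Optional[str] = None  # "up" | "down" | None


class TargetFileError(Exception):
    pass


def read_targets(path: str | Path, net: Network) -> list[TargetSpec]:
    """Parse a targets TSV (columns: entity, role, optional direction).

    Entities may be given by id or display name; unknown names raise with
    nearest-match suggestions.
    """
    by_name = {}
    for ent in net.entities.values():
        by_name.setdefault(ent.name.lower(), ent.id)
    specs = []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = [c.strip() for c in line.split("\t")]
        if lineno == 1 and cols[0].lower() == "entity":
            continue  # header row
        if len(cols) < 2:
            raise TargetFileError(f"line {lineno}: expected entity<TAB>role")
        name, role = cols[0], cols[1].lower()
        direction = cols[2].lower() if len(cols) > 2 and cols[2] else None
        if role not in ("condition", "effect"):
            raise TargetFileError(f"line {lineno}: role must be condition or effect")
        if direction not in (None, "up", "down"):
            raise TargetFileError(f"line {lineno}: direction must be up or down")
        if name in net.entities:
            eid = name
        elif name.lower() in by_name:
            eid = by_name[name.lower()]
        else:
            pool = list(net.entities) + [e.name for e in net.entities.values()]
            hint = get_close_matches(name, pool, n=3)
            suffix = f"; did you mean {', '.join(hint)}?" if hint else ""
            raise TargetFileError(f"line {lineno}: unknown entity {name!r}{suffix}")
        specs.append(TargetSpec(net.logical_node_of(eid), role, direction))
    return specs


@dataclass(frozen=True)
class PathRecord:
    """A simple path from an effect root through G1 to a terminus."""

    root: str
    terminus: str
    edges: tuple[InfluenceEdge, ...]
    total_cost: float
    parity: str  # "+", "-", "ambiguous"

    @classmethod
    def from_edges(cls, edges: Sequence[InfluenceEdge]) -> "PathRecord":
        return cls(
            root=edges[0].from_node,
            terminus=edges[-1].to_node,
            edges=tuple(edges),
            total_cost=sum(e.cost for e in edges),
            parity=combine_parity(e.sign for e in edges),
        )

    def node_sequence(self) -> tuple[str, ...]:
        return (self.root,) + tuple(e.to_node for e in self.edges)


def combine_parity(signs: Iterable[str]) -> str:
    """Sign product with 'ambiguous' absorbing."""
    parity = "+"
    for s in signs:
        if s == "ambiguous":
            return "ambiguous"
        if s == "-":
            parity = "-" if parity == "+" else "+"
    return parity


class PathList(list):
    """List of PathRecord with a truncation flag."""

    truncated: bool = False


def _distance_to(g1: MetRegGraph, terminus: str) -> dict[str, float]:
    """Exact shortest distance from every node to the terminus along stored
    edges (reverse Dijkstra); admissible pruning bound for enumeration."""
    rev: dict[str, list[tuple[str, float]]] = {}
    for e in g1.edges.values():
        rev.setdefault(e.to_node, []).append((e.from_node, e.cost))
    dist = {terminus: 0.0}
    heap = [(0.0, terminus)]
    while heap:
        d, n = heapq.heappop(heap)
        if d > dist.get(n, float("inf")) + _EPS:
            continue
        for m, c in rev.get(n, ()):
            nd = d + c
            if nd < dist.get(m, float("inf")) - _EPS:
                dist[m] = nd
                heapq.heappush(heap, (nd, m))
    return dist


def enumerate_paths(
    g1: MetRegGraph,
    root: str,
    terminus: str,
    offset: float = DEFAULT_OFFSET,
    max_paths: Optional[int] = DEFAULT_MAX_PATHS,
    hard_cap: int = 20000,
) -> PathList:
    """All simple paths root -> terminus within ``offset`` of the minimum.

    Bounded depth-first traversal with exact remaining-distance pruning;
    results sorted by (total cost, lexical edge provenance) and truncated at
    ``max_paths`` (the returned list carries a ``truncated`` flag).  An
    absent terminus yields an empty list.
    """
    result = PathList()
    if root not in g1.nodes or terminus not in g1.nodes:
        return result
    dist = _distance_to(g1, terminus)
    if root not in dist:
        return result
    bound = dist[root] + offset

    found: list[PathRecord] = []
    overflow = False

    def dfs(node: str, cost: float, visited: set[str], trail: list[InfluenceEdge]):
        nonlocal overflow
        if overflow:
            return
        if node == terminus:
            if trail:
                found.append(PathRecord.from_edges(trail))
                if len(found) > hard_cap:
                    overflow = True
            return
        for edge in sorted(g1.edges_from(node), key=lambda e: (e.to_node, e.via)):
            nxt = edge.to_node
            if nxt in visited:
                continue
            ncost = cost + edge.cost
            remaining = dist.get(nxt)
            if remaining is None or ncost + remaining > bound + _EPS:
                continue
            visited.add(nxt)
            trail.append(edge)
            dfs(nxt, ncost, visited, trail)
            trail.pop()
            visited.discard(nxt)

    dfs(root, 0.0, {root}, [])
    found.sort(key=lambda p: (p.total_cost, tuple(e.via for e in p.edges)))
    if max_paths is not None and len(found) > max_paths:
        result.extend(found[:max_paths])
        result.truncated = True
    else:
        result.extend(found)
        result.truncated = overflow
    return result


def parity_consistent(path: PathRecord, condition_dir: str, effect_dir: str) -> bool:
    """Does the path's net sign explain the observed directions of change?

    The influence runs condition -> effect, so a positive-parity path is
    consistent when both move the same way, a negative-parity path when they
    move oppositely; an ambiguous path (any reversible-reaction edge) can
    support either parity.
    """
    if condition_dir not in ("up", "down") or effect_dir not in ("up", "down"):
        raise ValueError(
            "parity filtering requires both directions; skip filtering instead"
        )
    if path.parity == "ambiguous":
        return True
    same = condition_dir == effect_dir
    return (path.parity == "+") == same


@dataclass
class FilteredGraph:
    """G2: the union of all kept paths, grouped per (effect, condition) pair."""

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple, InfluenceEdge] = field(default_factory=dict)
    kept_paths: dict[tuple[str, str], list[PathRecord]] = field(default_factory=dict)
    consistent_pairs: set[tuple[str, str]] = field(default_factory=set)
    truncated_pairs: set[tuple[str, str]] = field(default_factory=set)
    unconnected: tuple[str, ...] = ()

    def add_paths(self, effect: str, condition: str, paths: Sequence[PathRecord]):
        if not paths:
            return
        self.kept_paths[(effect, condition)] = list(paths)
        for p in paths:
            self.nodes.update(p.node_sequence())
            for e in p.edges:
                self.edges.setdefault(e.key, e)


def _reduce_paths(
    paths: PathList,
    max_paths: int,
    offset: float,
    condition_dir: Optional[str],
    effect_dir: Optional[str],
    use_parity: bool,
) -> tuple[list[PathRecord], bool]:
    """Reduction schedule when a pair has too many paths: parity filter first
    (when directions are known), then halve the offset down to 0, then hard
    truncation.  Returns (paths, truncated_by_count)."""
    kept: list[PathRecord] = list(paths)
    if len(kept) <= max_paths:
        return kept, paths.truncated
    if use_parity and condition_dir and effect_dir:
        kept = [p for p in kept if parity_consistent(p, condition_dir, effect_dir)]
    if kept:
        min_cost = kept[0].total_cost
        off = offset
        while len(kept) > max_paths and off > 1e-6:
            off /= 2
            kept = [p for p in kept if p.total_cost <= min_cost + off + _EPS]
        if len(kept) > max_paths:
            kept = [p for p in kept if p.total_cost <= min_cost + _EPS]
    if len(kept) > max_paths:
        return kept[:max_paths], True
    return kept, paths.truncated


def filter_directed(
    g1: MetRegGraph,
    conditions: Sequence[TargetSpec],
    effects: Sequence[TargetSpec],
    offset: float = DEFAULT_OFFSET,
    max_paths: int = DEFAULT_MAX_PATHS,
    use_parity: bool = True,
) -> FilteredGraph:
    """Build G2 from every (effect, condition) pair with paths in G1."""
    g2 = FilteredGraph()
    connected: set[str] = set()
    for eff in effects:
        if eff.entity not in g1.roots:
            continue
        for cond in conditions:
            if cond.entity not in g1.nodes or cond.entity == eff.entity:
                continue
            paths = enumerate_paths(g1, eff.entity, cond.entity, offset, None)
            kept, truncated = _reduce_paths(
                paths, max_paths, offset, cond.direction, eff.direction, use_parity
            )
            if not kept:
                continue
            pair = (eff.entity, cond.entity)
            g2.add_paths(eff.entity, cond.entity, kept)
            connected.update(pair)
            if truncated:
                g2.truncated_pairs.add(pair)
            if cond.direction and eff.direction and any(
                parity_consistent(p, cond.direction, eff.direction) for p in kept
            ):
                g2.consistent_pairs.add(pair)
    all_targets = [t.entity for t in list(effects) + list(conditions)]
    g2.unconnected = tuple(
        sorted({t for t in all_targets if t not in connected})
    )
    return g2


@dataclass(frozen=True)
class InfluencerScore:
    entity: str
    score: float
    reached: frozenset[str]
    per_target_cost: tuple[tuple[str, float], ...]  # sorted (target, cost) pairs


def score_influencers(
    g1: MetRegGraph,
    targets: Optional[Iterable[str]] = None,
    c_max: Optional[float] = None,
) -> list[InfluencerScore]:
    """Score every node reaching >= 2 targets; ascending (best first).

    score = sum of minimum path costs to reached targets
          + 1.5 * c_max per unreached target.
    Ties break by more targets reached, then id.
    """
    target_list = tuple(targets) if targets is not None else g1.roots
    if len(target_list) < 2:
        raise ValueError("undirected scoring needs at least two targets")
    c_max = g1.c_max if c_max is None else c_max
    scored = []
    for nid, node in g1.nodes.items():
        per = {t: node.PC[t] for t in target_list if t in node.PC}
        if len(per) < 2:
            continue
        score = sum(per.values()) + PENALTY_MULTIPLIER * c_max * (
            len(target_list) - len(per)
        )
        scored.append(
            InfluencerScore(
                entity=nid,
                score=score,
                reached=frozenset(per),
                per_target_cost=tuple(sorted(per.items())),
            )
        )
    scored.sort(key=lambda s: (s.score, -len(s.reached), s.entity))
    return scored


def top_influencers(
    ranked: Sequence[InfluencerScore], n: int = 10
) -> list[InfluencerScore]:
    return list(ranked[:n])


def covering_set(
    ranked: Sequence[InfluencerScore], targets: Iterable[str]
) -> tuple[list[InfluencerScore], set[str], set[str]]:
    """Greedy cover: walk the ascending ranking, keeping each influencer that
    adds at least one uncovered target.  Not necessarily minimal — better
    scoring influencers are preferred even at the price of redundancy.
    """
    target_set = set(targets)
    cover: list[InfluencerScore] = []
    covered: set[str] = set()
    for inf in ranked:
        gain = (inf.reached & target_set) - covered
        if gain:
            cover.append(inf)
            covered |= inf.reached & target_set
        if covered >= target_set:
            break
    return cover, covered, target_set - covered


def filter_undirected(
    g1: MetRegGraph,
    targets: Optional[Iterable[str]] = None,
    offset: float = DEFAULT_OFFSET,
    max_paths: int = DEFAULT_MAX_PATHS,
    c_max: Optional[float] = None,
    chosen_influencers: Optional[Iterable[str]] = None,
) -> tuple[list[InfluencerScore], FilteredGraph]:
    """Reduce undirected mode to directed mode via the covering set.

    ``chosen_influencers`` substitutes a user-selected influencer set for the
    greedy cover (mirrors reselecting from the ranked influencer list).
    """
    target_list = tuple(targets) if targets is not None else g1.roots
    ranked = score_influencers(g1, target_list, c_max)
    if chosen_influencers is not None:
        wanted = set(chosen_influencers)
        cover = [s for s in ranked if s.entity in wanted]
        missing = wanted - {s.entity for s in cover}
        if missing:
            raise KeyError(f"not in the influencer ranking: {sorted(missing)}")
    else:
        cover, _, _ = covering_set(ranked, target_list)
    conditions = [TargetSpec(s.entity, "condition") for s in cover]
    effects = [TargetSpec(t, "effect") for t in target_list]
    g2 = filter_directed(g1, conditions, effects, offset, max_paths, use_parity=False)
    return cover, g2


def format_path_report(
    g2: FilteredGraph,
    net: Network,
    conditions: Sequence[TargetSpec] = (),
    effects: Sequence[TargetSpec] = (),
) -> str:
    """Per-pair text report: each path as 'A -[type,sign]-> B ...' with its
    total cost and, when directions were supplied, a consistency flag."""
    dirs = {t.entity: t.direction for t in list(conditions) + list(effects)}

    def name(nid: str) -> str:
        ent = net.entities.get(nid)
        if ent is not None:
            return ent.display_name()
        return nid

    lines = []
    for (eff, cond), paths in sorted(g2.kept_paths.items()):
        header = f"== effect {name(eff)} <- condition {name(cond)} ({len(paths)} path(s))"
        if (eff, cond) in g2.truncated_pairs:
            header += " [truncated]"
        lines.append(header)
        cd, ed = dirs.get(cond), dirs.get(eff)
        for p in paths:
            hops = [name(p.root)]
            for e in p.edges:
                hops.append(f"-[{e.type},{e.sign}]-> {name(e.to_node)}")
            flag = ""
            if cd and ed:
                ok = parity_consistent(p, cd, ed)
                flag = "  consistent" if ok else "  inconsistent"
            lines.append(
                f"  cost {p.total_cost:.3f}  parity {p.parity}{flag}: "
                + " ".join(hops)
            )
        lines.append("")
    return "\n".join(lines)


def write_influencer_tsv(
    ranked: Sequence[InfluencerScore], path: str | Path, top_n: int = 10
) -> None:
    """Influencer ranking TSV with a top-N marker column."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("rank\tentity\tscore\tn_reached\ttargets\ttop_ten\n")
        for i, s in enumerate(ranked, start=1):
            fh.write(
                f"{i}\t{s.entity}\t{s.score:.4f}\t{len(s.reached)}\t"
                f"{';'.join(sorted(s.reached))}\t{int(i <= top_n)}\n"
            )
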