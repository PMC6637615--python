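import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from conftest import brute_force_paths

from metreg import (
    Entity,
    Network,
    Reaction,
    Regulation,
    TargetSpec,
    build_metreg_graph,
    combine_parity,
    covering_set,
    enumerate_paths,
    filter_directed,
    filter_undirected,
    parity_consistent,
    read_targets,
    score_influencers,
    write_network,
)
from metreg.path_filter import InfluencerScore, PENALTY_MULTIPLIER
from metreg.synth_networks import SynthParams, generate_network, toy_network


def regulator_cascade(depth, branch=False):
    """gene g0 regulated by tf1 regulated by tf2 ... (logical ids g0, gT1...)."""
    ents = [Entity(id="g0", kind="gene")]
    regs = []
    for i in range(1, depth + 1):
        ents.append(Entity(id=f"gT{i}", kind="gene"))
        ents.append(Entity(id=f"pT{i}", kind="protein", product_of=f"gT{i}"))
        target = "g0" if i == 1 else f"gT{i - 1}"
        regs.append(Regulation(f"r{i}", f"pT{i}", target, "transcriptional", "+"))
    return Network.from_records(ents, [], regs)


class TestEnumeratePaths:
    def test_single_direct_edge_offset_zero(self):
        net = regulator_cascade(1)
        g1 = build_metreg_graph(["g0"], net)
        paths = enumerate_paths(g1, "g0", "gT1", offset=0.0)
        assert len(paths) == 1
        assert paths[0].node_sequence() == ("g0", "gT1")

    def test_diamond_keeps_both_paths_within_offset(self):
        # two parallel 2-step regulator routes g0 <- A <- C and g0 <- B <- C
        ents = [Entity(id="g0", kind="gene")]
        regs = []
        for tf in ("A", "B", "C"):
            ents.append(Entity(id=f"g{tf}", kind="gene"))
            ents.append(Entity(id=f"p{tf}", kind="protein", product_of=f"g{tf}"))
        regs = [
            Regulation("r1", "pA", "g0", "transcriptional", "+"),
            Regulation("r2", "pB", "g0", "transcriptional", "+"),
            Regulation("r3", "pC", "gA", "transcriptional", "+"),
            Regulation("r4", "pC", "gB", "transcriptional", "+"),
            # make route B slightly costlier: pB also regulates a spare gene
            Regulation("r5", "pB", "gC", "transcriptional", "+"),
        ]
        net = Network.from_records(ents, [], regs)
        g1 = build_metreg_graph(["g0"], net)
        both = enumerate_paths(g1, "g0", "gC", offset=0.5)
        assert len(both) == 2
        assert both[0].total_cost <= both[1].total_cost
        only_best = enumerate_paths(g1, "g0", "gC", offset=0.0)
        assert len(only_best) == 1

    def test_absent_terminus_gives_empty_list(self):
        net = regulator_cascade(1)
        g1 = build_metreg_graph(["g0"], net)
        assert enumerate_paths(g1, "g0", "missing") == []

    def test_truncation_flag_and_min_path_always_kept(self):
        net = regulator_cascade(1)
        g1 = build_metreg_graph(["g0"], net)
        paths = enumerate_paths(g1, "g0", "gT1", offset=5.0, max_paths=1)
        assert len(paths) == 1 and not paths.truncated

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        """On small random networks, bounded DFS equals exhaustive simple-path
        enumeration under the same cost bound."""
        params = SynthParams(
            seed=seed,
            n_metabolites=6,
            n_reactions=8,
            n_enzymes=3,
            n_tfs=2,
            p_reversible=0.3,
            p_regulation=0.5,
            n_tus=1,
        )
        net = generate_network(params)
        roots = sorted(net.logical_node_of(e) for e in net.entities)[: 2]
        g1 = build_metreg_graph(roots, net, c_max=10.0, mode="undirected")
        offset = 2.5
        for root in g1.roots:
            termini = [n for n in sorted(g1.nodes) if n != root]
            for terminus in termini[seed % 3 :: 3]:
                got = enumerate_paths(g1, root, terminus, offset, max_paths=None)
                min_cost = min((p.total_cost for p in got), default=None)
                expected = (
                    []
                    if min_cost is None
                    else brute_force_paths(g1, root, terminus, min_cost + offset)
                )
                assert sorted(
                    (round(p.total_cost, 9), tuple(e.key for e in p.edges))
                    for p in got
                ) == sorted((round(c, 9), t) for c, t in expected)


class TestParity:
    def test_consistency_truth_table(self):
        plus = _path_with_parity("+")
        minus = _path_with_parity("-")
        amb = _path_with_parity("ambiguous")
        assert parity_consistent(plus, "up", "up")
        assert not parity_consistent(plus, "up", "down")
        assert parity_consistent(minus, "up", "down")
        assert not parity_consistent(minus, "down", "down")
        assert parity_consistent(amb, "up", "down")
        assert parity_consistent(amb, "down", "down")

    def test_unspecified_direction_is_an_error(self):
        with pytest.raises(ValueError):
            parity_consistent(_path_with_parity("+"), None, "up")

    def test_parity_is_sign_product_with_ambiguous_absorption(self):
        for k in range(1, 7):
            for signs in itertools.product(("+", "-", "ambiguous"), repeat=k):
                got = combine_parity(signs)
                if "ambiguous" in signs:
                    assert got == "ambiguous"
                else:
                    assert got == ("-" if signs.count("-") % 2 else "+")


def _path_with_parity(parity):
    from metreg.path_filter import PathRecord
    from metreg.influence_edges import InfluenceEdge

    sign = parity if parity != "+" else "+"
    e = InfluenceEdge("a", "b", "transcriptional-regulator", ("r", ""), sign, 1.0)
    return PathRecord("a", "b", (e,), 1.0, parity)


class TestFilterDirected:
    def test_unreachable_condition_reported(self):
        net = regulator_cascade(1)
        g1 = build_metreg_graph(["g0"], net)
        g2 = filter_directed(
            g1,
            [TargetSpec("missing", "condition")],
            [TargetSpec("g0", "effect")],
        )
        assert not g2.kept_paths
        assert "missing" in g2.unconnected and "g0" in g2.unconnected

    def test_g2_is_union_of_kept_path_nodes(self):
        net = toy_network()
        g1 = build_metreg_graph(["M0"], net, input_entities=["M0", "gTF0"])
        g2 = filter_directed(
            g1, [TargetSpec("gTF0", "condition")], [TargetSpec("M0", "effect")],
            offset=3.0,
        )
        expected_nodes = set()
        expected_edges = set()
        for paths in g2.kept_paths.values():
            for p in paths:
                expected_nodes.update(p.node_sequence())
                expected_edges.update(e.key for e in p.edges)
        assert g2.nodes == expected_nodes
        assert set(g2.edges) == expected_edges

    def test_parity_filter_applies_before_truncation(self):
        # two routes with opposite parity; with directions up/up only the
        # all-activating one survives a max_paths=1 budget
        ents = [Entity(id="g0", kind="gene")]
        regs = []
        for tf in ("A", "B", "C"):
            ents.append(Entity(id=f"g{tf}", kind="gene"))
            ents.append(Entity(id=f"p{tf}", kind="protein", product_of=f"g{tf}"))
        regs = [
            Regulation("r1", "pA", "g0", "transcriptional", "+"),
            Regulation("r3", "pC", "gA", "transcriptional", "+"),
            Regulation("r2", "pB", "g0", "transcriptional", "-"),
            Regulation("r4", "pC", "gB", "transcriptional", "+"),
        ]
        net = Network.from_records(ents, [], regs)
        g1 = build_metreg_graph(["g0"], net)
        g2 = filter_directed(
            g1,
            [TargetSpec("gC", "condition", "up")],
            [TargetSpec("g0", "effect", "up")],
            offset=2.0,
            max_paths=1,
        )
        (paths,) = g2.kept_paths.values()
        assert len(paths) == 1
        assert paths[0].parity == "+"
        assert ("g0", "gC") in g2.consistent_pairs


class TestInfluencerScoring:
    def test_score_without_penalty(self):
        g1 = _fake_g1(
            roots=("t1", "t2"),
            pcs={"n": {"t1": 2.0, "t2": 3.0}},
            c_max=20.0,
        )
        (s,) = score_influencers(g1, ("t1", "t2"))
        assert s.score == pytest.approx(5.0)

    def test_score_with_single_penalty(self):
        g1 = _fake_g1(
            roots=("t1", "t2", "t3"),
            pcs={"n": {"t1": 3.0, "t2": 1.0}},
            c_max=20.0,
        )
        scored = {s.entity: s for s in score_influencers(g1)}
        assert scored["n"].score == pytest.approx(3.0 + 1.0 + 1.5 * 20.0)

    def test_nodes_reaching_fewer_than_two_targets_are_unscored(self):
        g1 = _fake_g1(roots=("t1", "t2"), pcs={"n": {"t1": 3.0}}, c_max=20.0)
        assert [s.entity for s in score_influencers(g1)] == []

    def test_single_target_is_an_error(self):
        g1 = _fake_g1(roots=("t1",), pcs={}, c_max=20.0)
        with pytest.raises(ValueError):
            score_influencers(g1)


def _fake_g1(roots, pcs, c_max):
    from metreg.metreg_build import MetRegGraph, MetRegNode

    g = MetRegGraph(roots=tuple(roots), c_max=c_max, mode="undirected")
    for r in roots:
        g.nodes[r] = MetRegNode(id=r, C=0.0, PC={r: 0.0})
    for nid, pc in pcs.items():
        g.nodes[nid] = MetRegNode(id=nid, C=min(pc.values()), PC=dict(pc))
    return g


class TestCoveringSet:
    def _score(self, entity, score, reached):
        return InfluencerScore(
            entity, score, frozenset(reached), tuple((t, 1.0) for t in sorted(reached))
        )

    def test_first_influencer_covers_all(self):
        ranked = [self._score("A", 4.0, {"t1", "t2"}), self._score("B", 9.0, {"t1"})]
        cover, covered, uncovered = covering_set(ranked, {"t1", "t2"})
        assert [c.entity for c in cover] == ["A"]
        assert covered == {"t1", "t2"} and not uncovered

    def test_redundant_influencer_skipped(self):
        ranked = [
            self._score("A", 10.0, {"t1", "t2"}),
            self._score("B", 12.0, {"t2"}),
            self._score("C", 15.0, {"t3"}),
        ]
        cover, covered, uncovered = covering_set(ranked, {"t1", "t2", "t3"})
        assert [c.entity for c in cover] == ["A", "C"]
        assert not uncovered

    def test_empty_ranking_leaves_all_uncovered(self):
        cover, covered, uncovered = covering_set([], {"t1", "t2"})
        assert cover == [] and covered == set() and uncovered == {"t1", "t2"}

    def test_random_rankings_properties(self):
        """Cover correctness on random rankings: covered set is the union of
        cover members' reach, every member adds a new target, and scores are
        non-decreasing along the greedy order."""
        import random

        rng = random.Random(42)
        for _ in range(100):
            targets = {f"t{i}" for i in range(rng.randint(2, 6))}
            ranked = sorted(
                (
                    self._score(
                        f"n{j}",
                        rng.uniform(0, 50),
                        set(rng.sample(sorted(targets), rng.randint(1, len(targets)))),
                    )
                    for j in range(rng.randint(0, 12))
                ),
                key=lambda s: s.score,
            )
            cover, covered, uncovered = covering_set(ranked, targets)
            union = set().union(*(c.reached for c in cover)) if cover else set()
            assert covered == union & targets
            seen = set()
            prev = -1.0
            for c in cover:
                assert c.reached & targets - seen, "member added nothing"
                assert c.score >= prev
                prev = c.score
                seen |= c.reached & targets
            assert uncovered == targets - covered


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(0, 60, allow_nan=False),
            st.sets(st.sampled_from(["t1", "t2", "t3", "t4"]), min_size=1),
        ),
        max_size=12,
    ),
    st.sets(st.sampled_from(["t1", "t2", "t3", "t4"]), min_size=2),
)
def test_cover_invariants_on_generated_rankings(entries, targets):
    """Greedy-cover invariants hold for arbitrary scored rankings: no member
    is redundant, coverage equals the union of members' reach, and scores
    never decrease along the greedy order."""
    ranked = sorted(
        (
            InfluencerScore(f"n{j}", score, frozenset(reached), ())
            for j, (score, reached) in enumerate(entries)
        ),
        key=lambda s: s.score,
    )
    cover, covered, uncovered = covering_set(ranked, targets)
    union = set().union(*(c.reached for c in cover)) if cover else set()
    assert covered == union & targets
    assert uncovered == targets - covered
    seen, prev = set(), float("-inf")
    for c in cover:
        assert (c.reached & targets) - seen
        assert c.score >= prev
        seen |= c.reached & targets
        prev = c.score


class TestFilterUndirected:
    def test_hub_regulator_becomes_cover_and_conditions(self):
        # one TF regulating 3 of 4 target genes
        ents = [Entity(id=f"g{i}", kind="gene") for i in range(4)]
        ents += [
            Entity(id="gH", kind="gene"),
            Entity(id="pH", kind="protein", product_of="gH"),
        ]
        regs = [
            Regulation(f"r{i}", "pH", f"g{i}", "transcriptional", "+")
            for i in range(3)
        ]
        net = Network.from_records(ents, [], regs)
        targets = ["g0", "g1", "g2", "g3"]
        g1 = build_metreg_graph(targets, net, mode="undirected")
        cover, g2 = filter_undirected(g1)
        assert "gH" in {c.entity for c in cover}
        reached_targets = {c for pair in g2.kept_paths for c in pair}
        assert {"g0", "g1", "g2"} <= reached_targets
        assert "g3" in g2.unconnected

    def test_target_can_be_its_own_best_influencer(self):
        # g0 regulates the two other targets: a target inside the cover
        ents = [
            Entity(id="g0", kind="gene"),
            Entity(id="p0", kind="protein", product_of="g0"),
            Entity(id="g1", kind="gene"),
            Entity(id="g2", kind="gene"),
        ]
        regs = [
            Regulation("r1", "p0", "g1", "transcriptional", "+"),
            Regulation("r2", "p0", "g2", "transcriptional", "+"),
        ]
        net = Network.from_records(ents, [], regs)
        g1 = build_metreg_graph(["g0", "g1", "g2"], net, mode="undirected")
        ranked = score_influencers(g1)
        assert ranked[0].entity == "g0"
        cover, g2 = filter_undirected(g1)
        assert cover[0].entity == "g0"

    def test_mutually_unreachable_targets_all_unconnected(self):
        ents = [Entity(id="g0", kind="gene"), Entity(id="g1", kind="gene")]
        net = Network.from_records(ents)
        g1 = build_metreg_graph(["g0", "g1"], net, mode="undirected")
        cover, g2 = filter_undirected(g1)
        assert cover == []
        assert set(g2.unconnected) == {"g0", "g1"}


class TestReadTargets:
    def test_parse_roles_directions_and_names(self, tmp_path, toy):
        p = tmp_path / "targets.tsv"
        p.write_text("entity\trole\tdirection\nM0\teffect\tup\nTF0\tcondition\tdown\n")
        specs = read_targets(p, toy)
        assert specs == [
            TargetSpec("M0", "effect", "up"),
            TargetSpec("gTF0", "condition", "down"),
        ]

    def test_unknown_entity_suggests_near_matches(self, tmp_path, toy):
        p = tmp_path / "targets.tsv"
        p.write_text("TF9\tcondition\n")
        with pytest.raises(Exception, match="did you mean"):
            read_targets(p, toy)
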