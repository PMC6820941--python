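"""Orientation ILP, position LP and end pruning, checked against brute force.

The brute-force oracle enumerates all 2^n vertex orientation assignments; for
a fixed assignment an edge can be kept exactly when its type's constraint
holds (opposite-strand types need o_i != o_j, same-strand types o_i == o_j),
so the optimum is the max over assignments of the satisfied weight.
"""

import itertools
import random

import networkx as nx
import pytest

from lrstitch.contradiction_removal import (
    assert_simple_paths,
    prune_end_conflicts,
    remove_contradictions,
    solve_orientation,
    solve_positions,
)
from lrstitch.scaffold_graph import GraphEdge, OrientationType, ScaffoldGraph

TYPES = [OrientationType.FF, OrientationType.RR, OrientationType.FR, OrientationType.RF]


def make_graph(edges):
    """edges: iterable of (v_i, v_j, otype, gap, weight)."""
    g = ScaffoldGraph()
    for v_i, v_j, otype, gap, weight in edges:
        assert v_i < v_j, "tests use canonical vertex order"
        g.add_edge(GraphEdge(v_i=v_i, v_j=v_j, otype=otype, gap=gap, weight=weight))
    return g


def brute_force_orientation_objective(graph):
    vs = sorted(graph.vertices)
    best = 0
    for bits in itertools.product((0, 1), repeat=len(vs)):
        o = dict(zip(vs, bits))
        total = 0
        for e in graph.edges.values():
            if e.otype.same_strand:
                ok = o[e.v_i] == o[e.v_j]
            else:
                ok = o[e.v_i] != o[e.v_j]
            if ok:
                total += e.weight
        best = max(best, total)
    return best


def random_graph(rng, n_max=8, p=0.45, w_max=1000):
    n = rng.randrange(2, n_max + 1)
    vs = [f"v{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append(
                    (vs[i], vs[j], rng.choice(TYPES), rng.randrange(-200, 2000), rng.randrange(1, w_max))
                )
    return make_graph(edges)


def chain_graph(lengths, gaps, weights):
    """A contradiction-free FF chain v00 -> v01 -> ... with given gaps."""
    edges = []
    for k in range(len(gaps)):
        edges.append((f"v{k:02d}", f"v{k+1:02d}", OrientationType.FF, gaps[k], weights[k]))
    return make_graph(edges)


class TestOrientationILP:
    def test_consistent_triangle_keeps_all(self):
        g = make_graph(
            [
                ("a", "b", OrientationType.FF, 100, 10),
                ("b", "c", OrientationType.FF, 100, 10),
                ("a", "c", OrientationType.FF, 100, 10),
            ]
        )
        sol, pruned = solve_orientation(g)
        assert all(v == 1 for v in sol.eta.values())
        assert sol.o["a"] == sol.o["b"] == sol.o["c"]

    def test_contradicted_triangle_drops_lightest(self):
        # two FF edges (same strand) force o_a == o_b == o_c, so the FR edge
        # (opposite strands) cannot be satisfied; brute force gives 20
        g = make_graph(
            [
                ("a", "b", OrientationType.FF, 100, 10),
                ("b", "c", OrientationType.FF, 100, 10),
                ("a", "c", OrientationType.FR, 100, 3),
            ]
        )
        sol, pruned = solve_orientation(g)
        assert sol.eta[("a", "c")] == 0
        assert sol.objective == 20 == brute_force_orientation_objective(g)
        assert ("a", "c") not in pruned.edges

    def test_single_edge_always_kept(self):
        for otype in TYPES:
            g = make_graph([("a", "b", otype, 50, 7)])
            sol, pruned = solve_orientation(g)
            assert sol.eta[("a", "b")] == 1
            assert len(pruned.edges) == 1

    def test_matches_brute_force_on_random_graphs(self):
        rng = random.Random(1234)
        for _ in range(30):
            g = random_graph(rng)
            sol, _ = solve_orientation(g)
            assert sol.objective == pytest.approx(brute_force_orientation_objective(g))

    def test_kept_edges_satisfy_their_constraints(self):
        rng = random.Random(99)
        for _ in range(20):
            g = random_graph(rng)
            sol, pruned = solve_orientation(g)
            for e in pruned.edges.values():
                if e.otype.same_strand:
                    assert sol.o[e.v_i] == sol.o[e.v_j]
                else:
                    assert sol.o[e.v_i] != sol.o[e.v_j]


class TestPositionLP:
    def test_exact_chain_zero_residual(self):
        lengths = {"v00": 1000, "v01": 2000, "v02": 1500}
        g = chain_graph(lengths, gaps=[100, 250], weights=[900, 900])
        osol, g1 = solve_orientation(g)
        psol, g2 = solve_positions(g1, osol, lengths)
        assert all(phi == pytest.approx(1.0, abs=1e-6) for phi in psol.phi.values())
        # positions are cumulative len+gap sums from the anchor, up to a
        # whole-component reflection (the strand anchor may mirror the walk)
        p = psol.p
        forward = [0.0, 1100.0, 3350.0]  # 1000+100, then +2000+250
        mirrored = [0.0, -2100.0, -3850.0]  # same chain walked from v02
        got = [p["v00"], p["v01"], p["v02"]]
        assert got == pytest.approx(forward, abs=1e-6) or got == pytest.approx(
            mirrored, abs=1e-6
        )
        assert len(g2.edges) == 2

    def test_planted_transitive_contradiction_removed(self):
        lengths = {"v00": 1000, "v01": 2000, "v02": 1500}
        edges = [
            ("v00", "v01", OrientationType.FF, 100, 900),
            ("v01", "v02", OrientationType.FF, 250, 900),
            # consistent transitive gap would be 100+2000+250=2350; plant 7350
            ("v00", "v02", OrientationType.FF, 7350, 50),
        ]
        g = make_graph(edges)
        osol, g1 = solve_orientation(g)
        psol, g2 = solve_positions(g1, osol, lengths, max_gap_deviation=1000)
        assert set(g2.edges) == {("v00", "v01"), ("v01", "v02")}
        assert psol.deviation[("v00", "v02")] == pytest.approx(5000, abs=1e-5)

    def test_single_edge_component(self):
        lengths = {"a": 500, "b": 700}
        g = make_graph([("a", "b", OrientationType.RF, 80, 5)])
        osol, g1 = solve_orientation(g)
        psol, g2 = solve_positions(g1, osol, lengths)
        assert psol.phi[("a", "b")] == pytest.approx(1.0, abs=1e-6)
        assert psol.deviation[("a", "b")] == pytest.approx(0.0, abs=1e-6)

    def test_reverse_oriented_chain_recovered(self):
        # an RR chain is the same walk seen from the other strand; positions
        # must still be consistent and nothing removed
        lengths = {"v00": 1000, "v01": 2000}
        g = make_graph([("v00", "v01", OrientationType.RR, 100, 10)])
        osol, g1 = solve_orientation(g)
        psol, g2 = solve_positions(g1, osol, lengths)
        assert len(g2.edges) == 1
        assert psol.deviation[("v00", "v01")] == pytest.approx(0.0, abs=1e-6)


class TestEndPruning:
    def test_keep_heaviest_per_end(self):
        # both edges claim the 3' end of a
        g = make_graph(
            [
                ("a", "b", OrientationType.FF, 100, 800),
                ("a", "c", OrientationType.FF, 100, 300),
            ]
        )
        pruned = prune_end_conflicts(g)
        assert set(pruned.edges) == {("a", "b")}

    def test_different_ends_no_conflict(self):
        # b's 5' end from a, b's 3' end to c: a perfect chain is untouched
        g = make_graph(
            [
                ("a", "b", OrientationType.FF, 100, 800),
                ("b", "c", OrientationType.FF, 100, 300),
            ]
        )
        pruned = prune_end_conflicts(g)
        assert len(pruned.edges) == 2

    def test_cycle_broken_at_min_weight(self):
        g = make_graph(
            [
                ("a", "b", OrientationType.FF, 100, 5),
                ("b", "c", OrientationType.FF, 100, 4),
                ("a", "c", OrientationType.RF, 100, 3),
            ]
        )
        pruned = prune_end_conflicts(g)
        assert set(pruned.edges) == {("a", "b"), ("b", "c")}

    def test_weight_tie_breaks_by_contig_id(self):
        g = make_graph(
            [
                ("a", "c", OrientationType.FF, 100, 800),
                ("a", "b", OrientationType.FF, 100, 800),
            ]
        )
        pruned = prune_end_conflicts(g)
        assert set(pruned.edges) == {("a", "b")}


class TestFullStage:
    def test_contradiction_free_input_loses_nothing(self):
        lengths = {f"v{k:02d}": 1000 + 100 * k for k in range(5)}
        g = chain_graph(lengths, gaps=[50, 60, 70, 80], weights=[5, 6, 7, 8])
        cleaned, _, _, counts = remove_contradictions(g, lengths)
        assert counts["edges_out"] == 4
        assert counts["removed_orientation"] == 0
        assert counts["removed_position"] == 0
        assert counts["removed_end_pruning"] == 0

    def test_structural_invariant_on_fuzzed_graphs(self):
        rng = random.Random(2024)
        for _ in range(40):
            g = random_graph(rng, n_max=9, p=0.5)
            lengths = {v: rng.randrange(500, 5000) for v in g.vertices}
            cleaned, _, _, _ = remove_contradictions(g, lengths)
            assert_simple_paths(cleaned)  # raises on violation
            nxg = cleaned.to_networkx()
            assert nxg.number_of_edges() == 0 or nx.is_forest(nxg)
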