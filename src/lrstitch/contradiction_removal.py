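"""Removing contradictory edges: orientation ILP, position LP, end pruning.

Spurious edges (repeat leakage, alignment noise) reveal themselves as
orientation or position contradictions.  Orientation: each contig gets a
binary strand variable; an edge may only be kept (eta = 1) if the strands it
implies are realisable, and the solver keeps the maximum-weight consistent
edge set.  Position: each contig gets a coordinate; a big-M slack variable
per edge lets the LP sacrifice edges whose gap estimate cannot be laid out
consistently, and any edge whose realised deviation exceeds a threshold is
deleted.  Finally, at most one edge may leave each contig end, and residual
cycles are broken at their weakest edge, leaving only simple paths.

Both programs are solved exactly with scipy's HiGHS backend, once over the
whole graph (component by component) rather than iteratively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import networkx as nx
import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .scaffold_graph import PAIR_OF_TYPE, GraphEdge, ScaffoldGraph

logger = logging.getLogger(__name__)

LARGE_COMPONENT_WARN = 2000


@dataclass
class OrientationSolution:
    o: Dict[str, int] = field(default_factory=dict)
    eta: Dict[Tuple[str, str], int] = field(default_factory=dict)
    objective: float = 0.0


@dataclass
class PositionSolution:
    p: Dict[str, float] = field(default_factory=dict)
    phi: Dict[Tuple[str, str], float] = field(default_factory=dict)
    L: float = 0.0
    objective: float = 0.0
    deviation: Dict[Tuple[str, str], float] = field(default_factory=dict)


def _component_edges(graph: ScaffoldGraph, comp: List[str]) -> List[GraphEdge]:
    members = set(comp)
    return [graph.edges[p] for p in sorted(graph.edges) if p[0] in members]


def solve_orientation(graph: ScaffoldGraph) -> Tuple[OrientationSolution, ScaffoldGraph]:
    """Assign strands and drop orientation-contradicted edges.

    Per connected component, solve the binary program

        max  sum(w_ij * eta_ij)
        s.t. eta_ij <= o_i + o_j <= 2 - eta_ij   (opposite-strand edges)
             eta_ij - 1 <= o_i - o_j <= 1 - eta_ij  (same-strand edges)

    with one vertex per component pinned to o = 0 to break the global flip
    symmetry.  Edges with eta = 0 are removed from the graph.
    """
    sol = OrientationSolution()
    pruned = graph.copy()
    for comp in graph.components():
        if len(comp) > LARGE_COMPONENT_WARN:
            logger.warning("orientation ILP on large component (%d vertices)", len(comp))
        edges = _component_edges(graph, comp)
        if not edges:
            for v in comp:
                sol.o[v] = 0
            continue
        v_index = {v: i for i, v in enumerate(comp)}
        nv, ne = len(comp), len(edges)
        n = nv + ne
        c = np.zeros(n)
        rows: List[np.ndarray] = []
        lbs: List[float] = []
        ubs: List[float] = []
        for k, e in enumerate(edges):
            c[nv + k] = -float(e.weight)
            i, j = v_index[e.v_i], v_index[e.v_j]
            if e.otype.same_strand:
                # eta - 1 <= o_i - o_j <= 1 - eta
                r = np.zeros(n)
                r[i], r[j], r[nv + k] = 1.0, -1.0, -1.0
                rows.append(r)
                lbs.append(-1.0)
                ubs.append(np.inf)
                r = np.zeros(n)
                r[i], r[j], r[nv + k] = 1.0, -1.0, 1.0
                rows.append(r)
                lbs.append(-np.inf)
                ubs.append(1.0)
            else:
                # eta <= o_i + o_j <= 2 - eta
                r = np.zeros(n)
                r[i], r[j], r[nv + k] = 1.0, 1.0, -1.0
                rows.append(r)
                lbs.append(0.0)
                ubs.append(np.inf)
                r = np.zeros(n)
                r[i], r[j], r[nv + k] = 1.0, 1.0, 1.0
                rows.append(r)
                lbs.append(-np.inf)
                ubs.append(2.0)
        lb = np.zeros(n)
        ub = np.ones(n)
        ub[0] = 0.0  # anchor: first vertex of the component is forward
        res = milp(
            c=c,
            constraints=LinearConstraint(np.vstack(rows), lbs, ubs),
            integrality=np.ones(n),
            bounds=Bounds(lb, ub),
        )
        if not res.success:  # pragma: no cover - eta=0 everywhere is feasible
            raise RuntimeError(f"orientation ILP failed: {res.message}")
        x = np.rint(res.x).astype(int)
        for v, i in v_index.items():
            sol.o[v] = int(x[i])
        for k, e in enumerate(edges):
            keep = int(x[nv + k])
            sol.eta[e.pair] = keep
            if keep == 0:
                pruned.remove_edge(e.pair)
        sol.objective += -float(res.fun)
    return sol, pruned


def _directed(edge: GraphEdge, orientation: OrientationSolution) -> Tuple[str, str]:
    """Orient an edge so its tail precedes its head on the forward strand.

    The edge type fixes the read-frame orientations (ox, oy) of (v_i, v_j);
    if the solved strand of v_i matches ox the observation frame agrees with
    the global frame and v_i precedes v_j, otherwise the order reverses.
    """
    ox, _ = PAIR_OF_TYPE[edge.otype]
    if orientation.o[edge.v_i] == ox:
        return edge.v_i, edge.v_j
    return edge.v_j, edge.v_i


def solve_positions(
    graph: ScaffoldGraph,
    orientation: OrientationSolution,
    lengths: Dict[str, int],
    max_gap_deviation: float = 1000.0,
) -> Tuple[PositionSolution, ScaffoldGraph]:
    """Assign coordinates and drop position-contradicted edges.

    Per component, solve

        max  sum(w_ij * phi_ij)
        s.t. L(phi_ij - 1) <= p_j - p_i - len(c_i) - g_ij <= L(1 - phi_ij)
             phi_ij in [0, 1], one anchor p = 0

    with L one more than the component's total span, so the constraint is
    vacuous at phi = 0.  An edge whose realised deviation
    |p_j - p_i - len_i - g| exceeds ``max_gap_deviation`` is removed.
    """
    sol = PositionSolution()
    pruned = graph.copy()
    for comp in graph.components():
        edges = _component_edges(graph, comp)
        if not edges:
            for v in comp:
                sol.p[v] = 0.0
            continue
        v_index = {v: i for i, v in enumerate(comp)}
        nv, ne = len(comp), len(edges)
        n = nv + ne
        L = sum(lengths[v] for v in comp) + sum(abs(e.gap) for e in edges) + 1.0
        c = np.zeros(n)
        a_ub: List[np.ndarray] = []
        b_ub: List[float] = []
        directed: List[Tuple[str, str, float]] = []
        for k, e in enumerate(edges):
            c[nv + k] = -float(e.weight)
            tail, head = _directed(e, orientation)
            g = e.gap
            len_tail = lengths[tail]
            directed.append((tail, head, len_tail + g))
            i, j = v_index[tail], v_index[head]
            # p_j - p_i - L*phi <= len_i + g + L  is always true; binding sides:
            # upper: p_j - p_i + L*phi <= len_i + g + L
            r = np.zeros(n)
            r[j], r[i], r[nv + k] = 1.0, -1.0, L
            a_ub.append(r)
            b_ub.append(len_tail + g + L)
            # lower: p_i - p_j + L*phi <= L - len_i - g
            r = np.zeros(n)
            r[i], r[j], r[nv + k] = 1.0, -1.0, L
            a_ub.append(r)
            b_ub.append(L - len_tail - g)
        span = L
        bounds = [(-span, span)] * nv + [(0.0, 1.0)] * ne
        bounds[0] = (0.0, 0.0)  # anchor
        res = linprog(
            c,
            A_ub=np.vstack(a_ub),
            b_ub=np.asarray(b_ub),
            bounds=bounds,
            method="highs",
        )
        if not res.success:  # pragma: no cover - bounded by construction
            raise RuntimeError(f"position LP failed: {res.message}")
        x = res.x
        for v, i in v_index.items():
            sol.p[v] = float(x[i])
        sol.L = L
        sol.objective += -float(res.fun)
        for k, e in enumerate(edges):
            tail, head, offset = directed[k]
            dev = abs(sol.p[head] - sol.p[tail] - offset)
            sol.phi[e.pair] = float(x[nv + k])
            sol.deviation[e.pair] = dev
            if dev > max_gap_deviation:
                pruned.remove_edge(e.pair)
    return sol, pruned


def prune_end_conflicts(graph: ScaffoldGraph) -> ScaffoldGraph:
    """Enforce one edge per contig end, then break residual cycles.

    An edge survives the per-end stage only if it carries the highest weight
    at both ends it touches (ties break by the other endpoint's id).  The
    surviving graph has vertex degree <= 2; any remaining cycle is broken at
    its minimum-weight edge, so only simple paths remain.
    """
    buckets: Dict[Tuple[str, str], List[GraphEdge]] = {}
    for e in graph.edges.values():
        for v in (e.v_i, e.v_j):
            buckets.setdefault((v, e.end_at(v)), []).append(e)
    keep = set(graph.edges)
    for (v, _end), es in buckets.items():
        if len(es) <= 1:
            continue
        best = min(es, key=lambda e: (-e.weight, e.other(v)))
        for e in es:
            if e is not best:
                keep.discard(e.pair)
    pruned = graph.copy()
    for pair in list(pruned.edges):
        if pair not in keep:
            pruned.remove_edge(pair)
    # break cycles (each component is now a path or a single cycle)
    g = pruned.to_networkx()
    for cycle in nx.cycle_basis(g):
        pairs = []
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            pair = (a, b) if (a, b) in pruned.edges else (b, a)
            pairs.append(pair)
        victim = min(pairs, key=lambda p: (pruned.edges[p].weight, p))
        pruned.remove_edge(victim)
    return pruned


def assert_simple_paths(graph: ScaffoldGraph) -> None:
    """Structural postcondition: per-end degree <= 1 and no cycles."""
    seen_ends: Dict[Tuple[str, str], int] = {}
    for e in graph.edges.values():
        for v in (e.v_i, e.v_j):
            key = (v, e.end_at(v))
            seen_ends[key] = seen_ends.get(key, 0) + 1
    bad = [k for k, n in seen_ends.items() if n > 1]
    if bad:
        raise AssertionError(f"vertex ends with degree > 1: {bad}")
    g = graph.to_networkx()
    if g.number_of_edges() and not nx.is_forest(g):
        raise AssertionError("scaffold graph contains a cycle after pruning")


def remove_contradictions(
    graph: ScaffoldGraph,
    lengths: Dict[str, int],
    max_gap_deviation: float = 1000.0,
) -> Tuple[ScaffoldGraph, OrientationSolution, PositionSolution, Dict[str, int]]:
    """Run orientation ILP -> position LP -> end pruning, in that order."""
    n0 = len(graph.edges)
    osol, g1 = solve_orientation(graph)
    n1 = len(g1.edges)
    psol, g2 = solve_positions(g1, osol, lengths, max_gap_deviation)
    n2 = len(g2.edges)
    g3 = prune_end_conflicts(g2)
    n3 = len(g3.edges)
    assert_simple_paths(g3)
    counts = {
        "edges_in": n0,
        "removed_orientation": n0 - n1,
        "removed_position": n1 - n2,
        "removed_end_pruning": n2 - n3,
        "edges_out": n3,
    }
    return g3, osol, psol, counts
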