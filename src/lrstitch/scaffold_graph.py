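"""The weighted scaffold graph over unique contigs.

Each local scaffold is first projected onto its unique contigs (ambiguous
entries removed, gaps re-derived by summing the skipped gaps and contig
lengths).  Every adjacent unique pair then contributes one observation:
an orientation type, a gap and a weight equal to the smaller of the two
alignment lengths.  Observations for the same pair are aggregated into a
single edge by majority vote on orientation, mean gap over the winning class
and maximum weight.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from statistics import fmean
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx

from .classification import ContigClassification
from .io_formats import ContigSet
from .local_scaffolding import LocalScaffold, LocalScaffoldEntry

logger = logging.getLogger(__name__)


class OrientationType(enum.Enum):
    """Relative orientation of a canonical contig pair (v_i, v_j).

    FF: 3' of v_i joins 5' of v_j (both forward)
    RR: 5' of v_i joins 3' of v_j (both reverse)
    FR: 3' of v_i joins 3' of v_j (opposite strands)
    RF: 5' of v_i joins 5' of v_j (opposite strands)
    """

    FF = "FF"
    RR = "RR"
    FR = "FR"
    RF = "RF"

    @property
    def same_strand(self) -> bool:
        return self in (OrientationType.FF, OrientationType.RR)


# observation orientations (first along read, second along read) -> type
_TYPE_OF_PAIR = {
    (1, 1): OrientationType.FF,
    (0, 0): OrientationType.RR,
    (1, 0): OrientationType.FR,
    (0, 1): OrientationType.RF,
}
# inverse: type -> the read-frame orientations of (v_i, v_j)
PAIR_OF_TYPE = {t: p for p, t in _TYPE_OF_PAIR.items()}

# which end of each vertex the edge touches
_ENDS = {
    OrientationType.FF: ("3", "5"),
    OrientationType.RR: ("5", "3"),
    OrientationType.FR: ("3", "3"),
    OrientationType.RF: ("5", "5"),
}

# deterministic tie-break order for orientation vote
_TYPE_ORDER = {
    OrientationType.FF: 0,
    OrientationType.RR: 1,
    OrientationType.FR: 2,
    OrientationType.RF: 3,
}


@dataclass(frozen=True)
class PairObservation:
    """One local scaffold's evidence about a canonical contig pair."""

    v_i: str
    v_j: str
    otype: OrientationType
    gap: float
    weight: int
    read_id: str


def make_observation(
    first: str,
    o_first: int,
    second: str,
    o_second: int,
    gap: float,
    weight: int,
    read_id: str,
) -> Optional[PairObservation]:
    """Canonicalize a read-order pair observation to (min_id, max_id).

    Reversing the pair flips both orientations, mapping FF<->RR and keeping
    FR/RF fixed, so the stored edge is independent of read strand.
    """
    if first == second:
        return None
    if first < second:
        otype = _TYPE_OF_PAIR[(o_first, o_second)]
        return PairObservation(first, second, otype, gap, weight, read_id)
    otype = _TYPE_OF_PAIR[(1 - o_second, 1 - o_first)]
    return PairObservation(second, first, otype, gap, weight, read_id)


@dataclass
class GraphEdge:
    """A scaffold-graph edge: (v_i, v_j, orientation, gap, weight)."""

    v_i: str
    v_j: str
    otype: OrientationType
    gap: float
    weight: int
    support: List[Tuple[str, float, int]] = field(default_factory=list)

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.v_i, self.v_j)

    def other(self, v: str) -> str:
        return self.v_j if v == self.v_i else self.v_i

    def end_at(self, v: str) -> str:
        """Which end ('5' or '3') of contig v this edge attaches to."""
        ei, ej = _ENDS[self.otype]
        return ei if v == self.v_i else ej


class ScaffoldGraph:
    """Vertices are unique contig ids; at most one edge per vertex pair."""

    def __init__(self, vertices: Iterable[str] = ()):
        self.vertices: Set[str] = set(vertices)
        self.edges: Dict[Tuple[str, str], GraphEdge] = {}

    def add_edge(self, edge: GraphEdge) -> None:
        if edge.v_i == edge.v_j:
            raise ValueError("self edges are not allowed")
        self.vertices.add(edge.v_i)
        self.vertices.add(edge.v_j)
        self.edges[edge.pair] = edge

    def remove_edge(self, pair: Tuple[str, str]) -> None:
        del self.edges[pair]

    def edges_of(self, v: str) -> List[GraphEdge]:
        return [e for e in self.edges.values() if v in (e.v_i, e.v_j)]

    def degree(self, v: str) -> int:
        return len(self.edges_of(v))

    def copy(self) -> "ScaffoldGraph":
        g = ScaffoldGraph(self.vertices)
        g.edges = dict(self.edges)
        return g

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for (a, b), e in self.edges.items():
            g.add_edge(a, b, weight=e.weight)
        return g

    def components(self) -> List[List[str]]:
        return [sorted(c) for c in nx.connected_components(self.to_networkx())]

    def __len__(self) -> int:
        return len(self.vertices)


def project_unique(
    ls: LocalScaffold,
    classes: Dict[str, ContigClassification],
    contigs: ContigSet,
) -> LocalScaffold:
    """Drop non-unique entries, re-deriving gaps between the survivors.

    When entries p..s of the original local scaffold collapse onto the pair
    (p, s), the new gap is the sum of all skipped read-axis gaps plus the
    lengths of the skipped contigs; with nothing in between it is simply the
    original gap.
    """
    entries = ls.entries
    keep_idx = [i for i, e in enumerate(entries) if classes[e.contig_id].is_unique]
    projected: List[LocalScaffoldEntry] = []
    for k, p in enumerate(keep_idx):
        src = entries[p]
        if k + 1 < len(keep_idx):
            s = keep_idx[k + 1]
            gap = sum(entries[j].gap_to_next for j in range(p, s))
            gap += sum(contigs.length(entries[j].contig_id) for j in range(p + 1, s))
        else:
            gap = 0
        projected.append(
            LocalScaffoldEntry(
                contig_id=src.contig_id,
                orientation=src.orientation,
                gap_to_next=gap,
                aln_len=src.aln_len,
                sr_p=src.sr_p,
                er_p=src.er_p,
            )
        )
    return LocalScaffold(read_id=ls.read_id, entries=projected)


def aggregate_edge(observations: List[PairObservation]) -> Optional[GraphEdge]:
    """Aggregate all observations of one pair into a single edge.

    Observations are partitioned by orientation type; the largest class wins
    (ties: larger summed weight, then canonical order FF<RR<FR<RF).  The gap
    is the mean over the winning class, the weight its maximum.
    """
    if not observations:
        return None
    groups: Dict[OrientationType, List[PairObservation]] = {}
    for obs in observations:
        groups.setdefault(obs.otype, []).append(obs)
    winner = max(
        groups.items(),
        key=lambda kv: (len(kv[1]), sum(o.weight for o in kv[1]), -_TYPE_ORDER[kv[0]]),
    )
    otype, cls = winner
    v_i, v_j = cls[0].v_i, cls[0].v_j
    gap = fmean(o.gap for o in cls)
    weight = max(o.weight for o in cls)
    support = [(o.read_id, o.gap, o.weight) for o in cls]
    return GraphEdge(v_i=v_i, v_j=v_j, otype=otype, gap=gap, weight=weight, support=support)


def build_graph(
    LS: List[LocalScaffold],
    classes: Dict[str, ContigClassification],
    contigs: ContigSet,
) -> ScaffoldGraph:
    """Build the scaffold graph over unique contigs.

    Unaligned unique contigs stay as isolated vertices so they are emitted as
    singleton scaffolds downstream.
    """
    graph = ScaffoldGraph(cid for cid, c in classes.items() if c.is_unique)
    obs_by_pair: Dict[Tuple[str, str], List[PairObservation]] = {}
    for ls in LS:
        pls = project_unique(ls, classes, contigs)
        for a, b in zip(pls.entries, pls.entries[1:]):
            obs = make_observation(
                a.contig_id,
                a.orientation,
                b.contig_id,
                b.orientation,
                a.gap_to_next,
                min(a.aln_len, b.aln_len),
                ls.read_id,
            )
            if obs is None:
                logger.debug("self-adjacency for %s in read %s skipped", a.contig_id, ls.read_id)
                continue
            obs_by_pair.setdefault((obs.v_i, obs.v_j), []).append(obs)
    for pair in sorted(obs_by_pair):
        edge = aggregate_edge(obs_by_pair[pair])
        if edge is not None:
            graph.add_edge(edge)
    return graph


def write_edges_tsv(graph: ScaffoldGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("v_i\tv_j\torientation\tgap\tweight\tn_support\n")
        for (a, b) in sorted(graph.edges):
            e = graph.edges[(a, b)]
            fh.write(f"{a}\t{b}\t{e.otype.value}\t{e.gap:g}\t{e.weight}\t{len(e.support)}\n")


def write_dot(graph: ScaffoldGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("graph scaffold_graph {\n")
        for v in sorted(graph.vertices):
            fh.write(f'  "{v}";\n')
        for (a, b) in sorted(graph.edges):
            e = graph.edges[(a, b)]
            fh.write(
                f'  "{a}" -- "{b}" [label="{e.otype.value} g={e.gap:g} w={e.weight}"];\n'
            )
        fh.write("}\n")
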