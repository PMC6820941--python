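"""From cleaned graph to final scaffolds.

Four stages: extract the simple paths of the contradiction-free graph as
draft scaffolds; re-insert ambiguous contigs between adjacent unique contigs
wherever reads vote for a specific run; extend scaffold ends using mini
scaffold graphs built from the reads touching each terminal contig; and merge
scaffolds whose terminal ``t`` contigs coincide (also after reversal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .alignment_prep import Thresholds
from .classification import ContigClassification, Label, Reason, all_unique
from .contradiction_removal import remove_contradictions
from .io_formats import ContigSet
from .local_scaffolding import LocalScaffold, LocalScaffoldEntry, reverse_entries
from .scaffold_graph import ScaffoldGraph, build_graph

logger = logging.getLogger(__name__)


@dataclass
class ScaffoldPart:
    contig_id: str
    orientation: int  # 1 forward, 0 reverse
    gap_after: float  # signed estimate; 0 for the last part


@dataclass
class Scaffold:
    id: str
    parts: List[ScaffoldPart] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.parts)

    def contig_ids(self) -> List[str]:
        return [p.contig_id for p in self.parts]

    def signature(self) -> Tuple[Tuple[str, int], ...]:
        return tuple((p.contig_id, p.orientation) for p in self.parts)

    def reversed_copy(self) -> "Scaffold":
        parts: List[ScaffoldPart] = []
        n = len(self.parts)
        for k in range(n - 1, -1, -1):
            p = self.parts[k]
            gap = self.parts[k - 1].gap_after if k > 0 else 0.0
            parts.append(ScaffoldPart(p.contig_id, 1 - p.orientation, gap))
        return Scaffold(id=self.id, parts=parts)


def _walk_path(graph: ScaffoldGraph, comp: List[str]) -> Scaffold:
    """Walk one simple-path component from its lexicographically smaller
    endpoint, propagating orientations through the edge end types."""
    if len(comp) == 1:
        return Scaffold(id="", parts=[ScaffoldPart(comp[0], 1, 0.0)])
    degree = {v: len(graph.edges_of(v)) for v in comp}
    endpoints = sorted(v for v in comp if degree[v] == 1)
    start = endpoints[0]
    parts: List[ScaffoldPart] = []
    prev_pair: Optional[Tuple[str, str]] = None
    current = start
    first_edge = graph.edges_of(start)[0]
    # orient the start so that its linked end faces right
    orientation = 1 if first_edge.end_at(start) == "3" else 0
    while True:
        nxt = [e for e in graph.edges_of(current) if e.pair != prev_pair]
        if not nxt:
            parts.append(ScaffoldPart(current, orientation, 0.0))
            break
        edge = nxt[0]
        parts.append(ScaffoldPart(current, orientation, float(edge.gap)))
        current = edge.other(current)
        orientation = 1 if edge.end_at(current) == "5" else 0
        prev_pair = edge.pair
    return Scaffold(id="", parts=parts)


def _canonicalize(scaf: Scaffold) -> Scaffold:
    """Prefer the direction whose first contig is forward; tie-break on the
    smaller first contig id so emission is deterministic."""
    rev = scaf.reversed_copy()

    def key(s: Scaffold):
        return (-s.parts[0].orientation, s.parts[0].contig_id)

    return min((scaf, rev), key=key)


def extract_simple_paths(graph: ScaffoldGraph) -> List[Scaffold]:
    """One draft scaffold per maximal simple path; isolated vertices become
    singleton scaffolds."""
    drafts = [_canonicalize(_walk_path(graph, comp)) for comp in graph.components()]
    drafts.sort(key=lambda s: s.parts[0].contig_id)
    return drafts


def _scan_occurrences(
    entries: Sequence[LocalScaffoldEntry],
    u: ScaffoldPart,
    v: ScaffoldPart,
    classes: Dict[str, ContigClassification],
) -> List[Tuple[Tuple[Tuple[str, int], ...], List[int], int]]:
    """Find u...v runs whose intermediates are all non-unique.

    Returns (candidate, gaps, weight) per occurrence, where candidate is the
    oriented intermediate run, gaps has len(candidate)+1 entries (gap from u
    into the run, within-run gaps, gap from the run into v) and weight is the
    pair weight min(scl_u, scl_v).
    """
    found = []
    for iu, e in enumerate(entries):
        if e.contig_id != u.contig_id or e.orientation != u.orientation:
            continue
        run: List[LocalScaffoldEntry] = []
        iv = None
        for j in range(iu + 1, len(entries)):
            if classes[entries[j].contig_id].is_unique:
                if (
                    entries[j].contig_id == v.contig_id
                    and entries[j].orientation == v.orientation
                ):
                    iv = j
                break
            run.append(entries[j])
        if iv is None or not run:
            continue
        candidate = tuple((r.contig_id, r.orientation) for r in run)
        gaps = [entries[iu].gap_to_next] + [r.gap_to_next for r in run]
        weight = min(entries[iu].aln_len, entries[iv].aln_len)
        found.append((candidate, gaps, weight))
    return found


def insert_ambiguous(
    draft: Scaffold,
    LS: List[LocalScaffold],
    classes: Dict[str, ContigClassification],
    contigs: ContigSet,
) -> Scaffold:
    """Insert the best-supported run of ambiguous contigs into each junction.

    For every adjacent unique pair the local scaffolds (both strand readings)
    are scanned for occurrences of the pair separated only by non-unique
    contigs; each distinct oriented run is a candidate, the one supported by
    most local scaffolds wins (ties: larger pair weight, then lexicographic),
    and its gaps are copied from the maximal-weight supporting occurrence.
    """
    if len(draft.parts) < 2:
        return draft
    new_parts: List[ScaffoldPart] = [replace(draft.parts[0])]
    for u, v in zip(draft.parts, draft.parts[1:]):
        candidates: Dict[Tuple[Tuple[str, int], ...], List[Tuple[List[int], int]]] = {}
        for ls in sorted(LS, key=lambda l: l.read_id):
            for frame in (ls.entries, reverse_entries(ls.entries)):
                for candidate, gaps, weight in _scan_occurrences(frame, u, v, classes):
                    candidates.setdefault(candidate, []).append((gaps, weight))
        tail = replace(v)
        if candidates:
            best = min(
                candidates.items(),
                key=lambda kv: (-len(kv[1]), -max(w for _, w in kv[1]), kv[0]),
            )
            candidate, occurrences = best
            gaps, _ = max(occurrences, key=lambda gw: gw[1])
            head = new_parts[-1]
            head.gap_after = float(gaps[0])
            for (cid, ori), gap in zip(candidate, gaps[1:]):
                new_parts.append(ScaffoldPart(cid, ori, float(gap)))
        new_parts.append(tail)
    return Scaffold(id=draft.id, parts=new_parts)


def _mini_graph_paths(
    terminal_id: str,
    LS: List[LocalScaffold],
    contigs: ContigSet,
    thresholds: Thresholds,
) -> List[Scaffold]:
    """Build and clean a scaffold graph from only the local scaffolds that
    contain the terminal contig, treating every contig as a vertex."""
    selected = [ls for ls in LS if any(e.contig_id == terminal_id for e in ls.entries)]
    if not selected:
        return []
    mentioned = ContigSet()
    pseudo: Dict[str, ContigClassification] = {}
    for ls in selected:
        for e in ls.entries:
            if e.contig_id not in mentioned:
                mentioned.add(contigs[e.contig_id])
                pseudo[e.contig_id] = ContigClassification(
                    e.contig_id, label=Label.UNIQUE, reason=Reason.DEFAULT_UNIQUE
                )
    graph = build_graph(selected, pseudo, mentioned)
    lengths = {cid: mentioned.length(cid) for cid in mentioned}
    cleaned, _, _, _ = remove_contradictions(graph, lengths, thresholds.max_gap_deviation)
    return extract_simple_paths(cleaned)


def _aligned_path_around(
    paths: List[Scaffold], terminal: ScaffoldPart
) -> Optional[Tuple[List[ScaffoldPart], int]]:
    """Locate the mini path containing the terminal contig and flip it so the
    terminal's orientation matches the scaffold frame."""
    for path in paths:
        for idx, part in enumerate(path.parts):
            if part.contig_id == terminal.contig_id:
                if part.orientation != terminal.orientation:
                    path = path.reversed_copy()
                    idx = len(path.parts) - 1 - idx
                return path.parts, idx
    return None


def extend_ends(
    scaffold: Scaffold,
    LS: List[LocalScaffold],
    classes: Dict[str, ContigClassification],
    contigs: ContigSet,
    thresholds: Thresholds,
    placed_unique: Set[str],
) -> Tuple[Scaffold, bool]:
    """One extension attempt at each end; returns (scaffold, changed).

    A contig may be added if it is not already in this scaffold and, when
    unique, not already placed in any scaffold (ambiguous contigs may recur
    across scaffolds).
    """
    changed = False
    in_scaffold = set(scaffold.contig_ids())

    def allowed(cid: str) -> bool:
        if cid in in_scaffold:
            return False
        if classes[cid].is_unique and cid in placed_unique:
            return False
        return True

    for side in ("head", "tail"):
        terminal = scaffold.parts[0] if side == "head" else scaffold.parts[-1]
        paths = _mini_graph_paths(terminal.contig_id, LS, contigs, thresholds)
        located = _aligned_path_around(paths, terminal)
        if located is None:
            continue
        parts, idx = located
        if side == "head":
            ext = parts[:idx]
            kept: List[ScaffoldPart] = []
            for part in reversed(ext):  # nearest to the terminal first
                if not allowed(part.contig_id):
                    break
                kept.insert(0, part)
            if kept:
                scaffold.parts = [replace(p) for p in kept] + scaffold.parts
                changed = True
        else:
            ext = parts[idx + 1 :]
            kept = []
            for part in ext:
                if not allowed(part.contig_id):
                    break
                kept.append(part)
            if kept:
                scaffold.parts[-1].gap_after = parts[idx].gap_after
                new_tail = [replace(p) for p in kept]
                new_tail[-1].gap_after = 0.0
                scaffold.parts = scaffold.parts + new_tail
                changed = True
        if changed:
            in_scaffold = set(scaffold.contig_ids())
            for part in scaffold.parts:
                if classes[part.contig_id].is_unique:
                    placed_unique.add(part.contig_id)
    return scaffold, changed


def _try_merge(a: Scaffold, b: Scaffold, t: int) -> Optional[Scaffold]:
    """Merge when a's last t parts equal b's first t parts (ids and
    orientations); gaps inside the overlap are averaged."""
    if len(a.parts) < t or len(b.parts) < t or a.id == b.id:
        return None
    tail = a.parts[-t:]
    head = b.parts[:t]
    for pa, pb in zip(tail, head):
        if pa.contig_id != pb.contig_id or pa.orientation != pb.orientation:
            return None
    overlap: List[ScaffoldPart] = []
    for k in range(t):
        if k < t - 1:
            gap = (tail[k].gap_after + head[k].gap_after) / 2.0
        else:
            gap = head[k].gap_after
        overlap.append(ScaffoldPart(tail[k].contig_id, tail[k].orientation, gap))
    parts = [replace(p) for p in a.parts[:-t]] + overlap + [replace(p) for p in b.parts[t:]]
    return Scaffold(id=a.id, parts=parts)


def merge_scaffolds(
    scaffolds: List[Scaffold],
    t: int,
    classes: Optional[Dict[str, ContigClassification]] = None,
) -> List[Scaffold]:
    """Merge scaffolds sharing t terminal contigs, to fixpoint.

    Each ordered pair is attempted with the second scaffold as-is and
    reversed.  A merge that would duplicate a unique contig outside the
    overlap is rejected when classifications are available.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    pool = {s.id: s for s in scaffolds}

    def merged_ok(m: Scaffold) -> bool:
        if classes is None:
            return True
        seen: Set[str] = set()
        for p in m.parts:
            cls = classes.get(p.contig_id)
            if cls is not None and cls.is_unique:
                if p.contig_id in seen:
                    return False
                seen.add(p.contig_id)
        return True

    changed = True
    while changed:
        changed = False
        ids = sorted(pool)
        for ai in ids:
            if ai not in pool:
                continue
            for bi in ids:
                if bi == ai or bi not in pool or ai not in pool:
                    continue
                a, b = pool[ai], pool[bi]
                for bv in (b, b.reversed_copy()):
                    m = _try_merge(a, bv, t)
                    if m is not None and merged_ok(m):
                        pool[ai] = m
                        del pool[bi]
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break
    return [pool[i] for i in sorted(pool)]


def build_scaffolds(
    graph: ScaffoldGraph,
    LS: List[LocalScaffold],
    classes: Dict[str, ContigClassification],
    contigs: ContigSet,
    thresholds: Thresholds,
    max_extension_passes: int = 10,
) -> List[Scaffold]:
    """Full scaffold generation: paths, insertion, extension, merging."""
    drafts = extract_simple_paths(graph)
    for k, d in enumerate(drafts):
        d.id = f"draft_{k}"
    drafts = [insert_ambiguous(d, LS, classes, contigs) for d in drafts]
    placed_unique: Set[str] = {
        p.contig_id
        for d in drafts
        for p in d.parts
        if classes[p.contig_id].is_unique
    }
    for _ in range(max_extension_passes):
        any_change = False
        for d in drafts:
            d, changed = extend_ends(d, LS, classes, contigs, thresholds, placed_unique)
            any_change = any_change or changed
        if not any_change:
            break
    merged = merge_scaffolds(drafts, thresholds.t, classes)
    merged.sort(key=lambda s: (-len(s.parts), s.parts[0].contig_id))
    out = []
    for k, s in enumerate(merged, start=1):
        out.append(Scaffold(id=f"scaffold_{k}", parts=s.parts))
    return out
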