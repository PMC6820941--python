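"""Per-read local scaffolds: ordering, end deduplication, redundancy pruning.

Every long read that carries reliable alignments induces a *local scaffold*:
the contigs it touches, ordered by revised read-start, each with an
orientation, the read-axis gap to its successor and its alignment length.
Local scaffolds are the raw material for both contig classification and the
scaffold graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from .alignment_prep import RevisedAlignment
from .io_formats import ContigSet, LongReadInfo


@dataclass
class LocalScaffoldEntry:
    """One contig occurrence along a read.

    orientation: 1 forward / 0 reverse alignment against the read.
    gap_to_next: signed read-axis distance to the next entry's revised
                 interval (0 for the last entry; negative means overlap).
    aln_len:     pre-revision span on the read (er - sr).
    """

    contig_id: str
    orientation: int
    gap_to_next: int
    aln_len: int
    sr_p: int = -1
    er_p: int = -1


@dataclass
class LocalScaffold:
    read_id: str
    entries: List[LocalScaffoldEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def reverse_entries(entries: List[LocalScaffoldEntry]) -> List[LocalScaffoldEntry]:
    """The same walk read off the opposite strand: order reversed,
    orientations flipped, gaps shifted to stay 'gap to next'."""
    rev: List[LocalScaffoldEntry] = []
    n = len(entries)
    for k, e in enumerate(reversed(entries)):
        src_idx = n - 1 - k
        gap = entries[src_idx - 1].gap_to_next if src_idx > 0 else 0
        rev.append(
            LocalScaffoldEntry(
                contig_id=e.contig_id,
                orientation=1 - e.orientation,
                gap_to_next=gap,
                aln_len=e.aln_len,
            )
        )
    return rev


def dedupe_read_ends(
    alns: List[RevisedAlignment], read_length: int
) -> List[RevisedAlignment]:
    """When several contigs claim the same read end, keep the longest match.

    Among alignments whose revised interval starts at read position 0 only
    the one with the greatest alignment length survives; symmetrically for
    alignments whose revised interval ends at the last read position.  Ties
    break on lexicographically smaller contig id.
    """

    def best(group: List[RevisedAlignment]) -> RevisedAlignment:
        return min(group, key=lambda a: (-a.aln_len, a.contig_id))

    out = list(alns)
    left = [a for a in out if a.sr_p == 0]
    if len(left) > 1:
        keep = best(left)
        out = [a for a in out if a.sr_p != 0 or a is keep]
    right = [a for a in out if a.er_p == read_length - 1]
    if len(right) > 1:
        keep = best(right)
        out = [a for a in out if a.er_p != read_length - 1 or a is keep]
    return out


def build_local_scaffold(
    read: LongReadInfo, alns: List[RevisedAlignment]
) -> Optional[LocalScaffold]:
    """Turn one read's reliable alignments into a local scaffold.

    Entries are ordered by revised read start; the gap between consecutive
    entries is the signed distance between their revised read intervals.
    Returns None when no reliable alignment survives.
    """
    kept = [a for a in alns if a.reliable]
    kept = dedupe_read_ends(kept, read.length)
    if not kept:
        return None
    kept.sort(key=lambda a: (a.sr_p, a.er_p, a.contig_id))
    entries: List[LocalScaffoldEntry] = []
    for i, a in enumerate(kept):
        if i + 1 < len(kept):
            gap = kept[i + 1].sr_p - a.er_p - 1
        else:
            gap = 0
        entries.append(
            LocalScaffoldEntry(
                contig_id=a.contig_id,
                orientation=a.strand,
                gap_to_next=gap,
                aln_len=a.aln_len,
                sr_p=a.sr_p,
                er_p=a.er_p,
            )
        )
    return LocalScaffold(read_id=read.id, entries=entries)


# Witness key: (first contig, its orientation, last contig, its orientation).
_WitnessKey = Tuple[str, int, str, int]


def _witness_index(
    LS: List[LocalScaffold], contigs: ContigSet
) -> Dict[_WitnessKey, List[Tuple[int, int]]]:
    """Index every consecutive triple (X, Y, Z), in both strand readings,
    by its flanking pair; the value is LEN(Y) + gap(Y->Z) in that reading."""
    index: Dict[_WitnessKey, List[Tuple[int, int]]] = {}
    for idx, ls in enumerate(LS):
        es = ls.entries
        for j in range(len(es) - 2):
            x, y, z = es[j], es[j + 1], es[j + 2]
            len_y = contigs.length(y.contig_id)
            key_fwd = (x.contig_id, x.orientation, z.contig_id, z.orientation)
            index.setdefault(key_fwd, []).append((len_y + y.gap_to_next, idx))
            key_rev = (z.contig_id, 1 - z.orientation, x.contig_id, 1 - x.orientation)
            index.setdefault(key_rev, []).append((len_y + x.gap_to_next, idx))
    return index


def prune_redundant_local_scaffolds(
    LS: List[LocalScaffold], contigs: ContigSet
) -> List[LocalScaffold]:
    """Remove local scaffolds superseded by a longer consistent witness.

    A local scaffold holding an adjacent pair (A, C) at gap g is removed when
    another local scaffold orders (A, B, C) with matching orientations of A
    and C and LEN(B) + gap(B, C) < g: the longer witness explains the gap and
    the shorter one almost certainly skipped B through alignment dropout.
    The rule is applied to every adjacent pair of every local scaffold.
    """
    index = _witness_index(LS, contigs)
    kept: List[LocalScaffold] = []
    for i, ls in enumerate(LS):
        remove = False
        es = ls.entries
        for j in range(len(es) - 1):
            a, c = es[j], es[j + 1]
            key = (a.contig_id, a.orientation, c.contig_id, c.orientation)
            for value, src in index.get(key, []):
                if src != i and value < a.gap_to_next:
                    remove = True
                    break
            if remove:
                break
        if not remove:
            kept.append(ls)
    return kept
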