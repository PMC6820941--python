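"""Length filters, alignment coordinate revision, reliability, containment.

Long-read aligners routinely clip the noisy ends of an alignment, so the
reported interval underestimates the true extent of the match.  The revision
step extrapolates each alignment outward until it hits position 0 of either
sequence on the left and the last position of either sequence on the right,
under the assumption that read and contig advance base-for-base.  An
alignment is then *reliable* when its mapping quality, aligned span and the
size of that extrapolation all pass their thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Set

from .io_formats import ContigSet, LongReadInfo, RawAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """All tunable cutoffs of the pipeline.

    s_m   -- minimum mapping quality, exclusive (reliability criterion i)
    l_m   -- minimum aligned span on read and contig, exclusive (criterion ii)
    alpha -- maximum coordinate shift introduced by revision, exclusive
             (criterion iii)
    L_r / L_c -- minimum read / contig length, exclusive
    L_ca  -- contigs shorter than this are ambiguous outright
    t     -- number of shared terminal contigs required to merge scaffolds
    containment_fraction -- coverage fraction above which a contig aligned
             inside a strictly longer contig is dropped as contained
    max_gap_deviation -- positional deviation (bp) above which an edge is
             removed after the position LP
    """

    s_m: int = 20
    l_m: int = 100
    alpha: int = 150
    L_r: int = 500
    L_c: int = 200
    L_ca: int = 1000
    t: int = 2
    containment_fraction: float = 0.95
    max_gap_deviation: int = 1000

    def __post_init__(self):
        for name in ("s_m", "l_m", "alpha", "L_r", "L_c", "L_ca", "t"):
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be >= 0")
        if not self.l_m < self.L_c:
            raise ValueError("l_m must be smaller than L_c")


@dataclass
class RevisedAlignment(RawAlignment):
    """A raw alignment plus its outward-extrapolated coordinates.

    ``[sr_p, er_p]`` / ``[sc_p, ec_p]`` are the revised read / contig
    intervals; ``aln_len`` is the pre-revision span on the read axis
    (``er - sr``), which is the shared axis used for edge weighting.

    Invariants (in the alignment-colinear frame; for reverse-strand records
    the read interval is mirrored onto the stored orientation first):
    the revised interval contains the original on both axes, the left
    extension reaches position 0 of read or contig, the right extension
    reaches the last position of read or contig, and the shift applied to
    the two axes is identical on each side.
    """

    sr_p: int = 0
    er_p: int = 0
    sc_p: int = 0
    ec_p: int = 0
    aln_len: int = 0
    reliable: bool = False


def filter_by_length(
    alignments: Iterable[RawAlignment],
    contigs: ContigSet,
    reads: Dict[str, LongReadInfo],
    thresholds: Thresholds,
) -> List[RawAlignment]:
    """Keep alignments whose read is longer than L_r and contig longer than L_c.

    Both comparisons are strict: a read of exactly L_r bases is dropped.
    """
    return [
        a
        for a in alignments
        if reads[a.read_id].length > thresholds.L_r
        and contigs.length(a.contig_id) > thresholds.L_c
    ]


def revise_alignment(a: RawAlignment, len_read: int, len_contig: int) -> RevisedAlignment:
    """Extrapolate an alignment to the ends of read or contig.

    Left side: whichever of read/contig has less unaligned sequence before
    the alignment is extended to position 0 and the other shifted by the same
    amount.  Right side symmetric: whichever has less unaligned sequence
    after the alignment is extended to its last position (``LEN - 1``) and
    the other endpoint shifted by that same distance.  Applying the same
    shift to both axes keeps the two intervals in register and makes
    revision idempotent.

    The extrapolation is co-linear: read and contig advance together.  For a
    reverse-strand alignment the read's left end pairs with the contig's
    *right* end, so the formula is applied in the mirrored read frame and the
    result mapped back onto the read's original axis.
    """
    if a.strand == 1:
        sr, er = a.sr, a.er
    else:
        sr, er = len_read - 1 - a.er, len_read - 1 - a.sr
    if sr < a.sc:
        sr_p = 0
        sc_p = a.sc - sr
    else:
        sc_p = 0
        sr_p = sr - a.sc
    if len_read - er > len_contig - a.ec:
        shift = len_contig - 1 - a.ec
        er_p = er + shift
        ec_p = len_contig - 1
    else:
        shift = len_read - 1 - er
        ec_p = a.ec + shift
        er_p = len_read - 1
    if a.strand == 0:
        sr_p, er_p = len_read - 1 - er_p, len_read - 1 - sr_p
    return RevisedAlignment(
        read_id=a.read_id,
        contig_id=a.contig_id,
        sr=a.sr,
        er=a.er,
        sc=a.sc,
        ec=a.ec,
        strand=a.strand,
        mapq=a.mapq,
        sr_p=sr_p,
        er_p=er_p,
        sc_p=sc_p,
        ec_p=ec_p,
        aln_len=a.er - a.sr,
        reliable=False,
    )


def is_reliable(r: RevisedAlignment, thresholds: Thresholds) -> bool:
    """Reliability test (all strict inequalities):

    i)   mapq > s_m;
    ii)  er-sr > l_m and ec-sc > l_m;
    iii) every revised coordinate moved by less than alpha.
    """
    if not r.mapq > thresholds.s_m:
        return False
    if not (r.er - r.sr > thresholds.l_m and r.ec - r.sc > thresholds.l_m):
        return False
    shifts = (r.sr - r.sr_p, r.er_p - r.er, r.sc - r.sc_p, r.ec_p - r.ec)
    return all(abs(s) < thresholds.alpha for s in shifts)


def revise_and_flag(
    alignments: Iterable[RawAlignment],
    contigs: ContigSet,
    reads: Dict[str, LongReadInfo],
    thresholds: Thresholds,
) -> List[RevisedAlignment]:
    """Convenience wrapper: revise every alignment and set its reliable flag."""
    out = []
    for a in alignments:
        r = revise_alignment(a, reads[a.read_id].length, contigs.length(a.contig_id))
        out.append(replace(r, reliable=is_reliable(r, thresholds)))
    return out


def drop_contained_contigs(
    contig_self_alignments: Iterable[RawAlignment] | None,
    contigs: ContigSet,
    containment_fraction: float = 0.95,
) -> Set[str]:
    """Flag contigs almost fully aligned inside a strictly longer contig.

    ``contig_self_alignments`` are contig-vs-contig records (query contig in
    the ``read_id`` field).  When no self-alignments are supplied the step is
    skipped and an empty set returned.
    """
    if not contig_self_alignments:
        logger.info("no contig self-alignments supplied; containment removal skipped")
        return set()
    contained: Set[str] = set()
    for a in contig_self_alignments:
        if a.read_id == a.contig_id:
            continue
        if a.read_id not in contigs or a.contig_id not in contigs:
            continue
        qlen = contigs.length(a.read_id)
        tlen = contigs.length(a.contig_id)
        coverage = (a.er - a.sr + 1) / qlen
        if coverage >= containment_fraction and tlen > qlen:
            contained.add(a.read_id)
    return contained
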