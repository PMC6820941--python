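"""Classifying contigs into unique and ambiguous from local-scaffold context.

A collapsed repeat shows a characteristic signature in the local scaffolds:
it sits in the *middle* of several reads whose flanking contigs differ, so it
accumulates more than one distinct 5'-end (or 3'-end) neighbour.  Such
contigs, and all contigs shorter than L_ca, are labelled ambiguous and kept
out of the scaffold graph; everything else is unique.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Set

from .alignment_prep import Thresholds
from .io_formats import ContigSet
from .local_scaffolding import LocalScaffold


class Label(enum.Enum):
    UNIQUE = "UNIQUE"
    AMBIGUOUS = "AMBIGUOUS"


class Reason(enum.Enum):
    SHORT = "SHORT"
    MULTI_NEIGHBOUR = "MULTI_NEIGHBOUR"
    DEFAULT_UNIQUE = "DEFAULT_UNIQUE"


@dataclass
class ContigClassification:
    contig_id: str
    label: Label | None = None
    reason: Reason | None = None
    five_prime_neighbours: Set[str] = field(default_factory=set)
    three_prime_neighbours: Set[str] = field(default_factory=set)
    middle_count: int = 0

    @property
    def is_unique(self) -> bool:
        return self.label is Label.UNIQUE


def neighbour_census(
    LS: List[LocalScaffold], contigs: ContigSet, thresholds: Thresholds
) -> Dict[str, ContigClassification]:
    """Accumulate 5'/3' neighbour sets over middle-position occurrences.

    Contigs shorter than L_ca are dropped from each local scaffold before the
    census (they are restored later, at ambiguous-contig insertion).  For a
    middle occurrence with forward orientation the predecessor along the read
    is the 5'-end neighbour and the successor the 3'-end neighbour; for a
    reverse occurrence the roles swap.
    """
    census = {cid: ContigClassification(cid) for cid in contigs}
    for ls in LS:
        view = [e for e in ls.entries if contigs.length(e.contig_id) >= thresholds.L_ca]
        for j in range(1, len(view) - 1):
            e = view[j]
            cls = census[e.contig_id]
            cls.middle_count += 1
            prev_id = view[j - 1].contig_id
            next_id = view[j + 1].contig_id
            if e.orientation == 1:
                cls.five_prime_neighbours.add(prev_id)
                cls.three_prime_neighbours.add(next_id)
            else:
                cls.three_prime_neighbours.add(prev_id)
                cls.five_prime_neighbours.add(next_id)
    return census


def classify_contigs(
    census: Dict[str, ContigClassification],
    contigs: ContigSet,
    thresholds: Thresholds,
) -> Dict[str, ContigClassification]:
    """Assign UNIQUE/AMBIGUOUS labels.

    AMBIGUOUS(SHORT) when the contig is shorter than L_ca (strict);
    AMBIGUOUS(MULTI_NEIGHBOUR) when it occurs in a middle position at least
    once *and* has more than one distinct 5'-end or 3'-end neighbour;
    UNIQUE otherwise (including contigs that never aligned, which end up as
    singleton scaffolds).
    """
    for cid in contigs:
        cls = census[cid]
        if contigs.length(cid) < thresholds.L_ca:
            cls.label = Label.AMBIGUOUS
            cls.reason = Reason.SHORT
        elif cls.middle_count >= 1 and (
            len(cls.five_prime_neighbours) > 1 or len(cls.three_prime_neighbours) > 1
        ):
            cls.label = Label.AMBIGUOUS
            cls.reason = Reason.MULTI_NEIGHBOUR
        else:
            cls.label = Label.UNIQUE
            cls.reason = Reason.DEFAULT_UNIQUE
    return census


def all_unique(contigs: ContigSet) -> Dict[str, ContigClassification]:
    """Degenerate classification treating every contig as unique (the
    no-classification ablation mode)."""
    return {
        cid: ContigClassification(cid, label=Label.UNIQUE, reason=Reason.DEFAULT_UNIQUE)
        for cid in contigs
    }


def write_classes_tsv(census: Dict[str, ContigClassification], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tlabel\treason\tn5\tn3\tmiddle_count\n")
        for cid in sorted(census):
            c = census[cid]
            fh.write(
                f"{cid}\t{c.label.value if c.label else ''}\t"
                f"{c.reason.value if c.reason else ''}\t"
                f"{len(c.five_prime_neighbours)}\t{len(c.three_prime_neighbours)}\t"
                f"{c.middle_count}\n"
            )
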