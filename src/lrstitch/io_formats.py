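"""Reading contigs and long-read alignments; writing scaffold FASTA and layout tables.

Coordinate convention
---------------------
Every interval in this package is 0-based with *inclusive* endpoints, so a
sequence of length ``L`` spans ``[0, L-1]``.  SAM's 1-based reference
coordinates and clip-aware query offsets are converted at this boundary and
never appear downstream.  Read coordinates are always expressed on the read's
*original* orientation (for reverse-strand records the stored query offsets
are mirrored), so that each read defines a single consistent axis along which
contigs can be ordered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, Iterator, List, Tuple

import pysam
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .scaffold_builder import Scaffold

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# CIGAR operation codes that consume the query / the reference.
_QUERY_OPS = {0, 1, 7, 8}  # M, I, =, X
_CLIP_OPS = {4, 5}  # S, H


class FastaError(ValueError):
    """Raised for structurally invalid FASTA input."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """A contiguous assembled sequence fragment."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class ContigSet:
    """An id-indexed collection of contigs with unique ids."""

    def __init__(self, contigs: List[Contig] | None = None):
        self._contigs: Dict[str, Contig] = {}
        for c in contigs or []:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.length == 0:
            raise ValidationError(f"contig {contig.id!r} has empty sequence")
        if contig.id in self._contigs:
            raise ValidationError(f"duplicate contig id {contig.id!r}")
        self._contigs[contig.id] = contig

    def __getitem__(self, cid: str) -> Contig:
        return self._contigs[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self._contigs

    def __len__(self) -> int:
        return len(self._contigs)

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def ids(self) -> List[str]:
        return list(self._contigs)

    def length(self, cid: str) -> int:
        return self._contigs[cid].length


@dataclass(frozen=True)
class LongReadInfo:
    """Identity and length of one long read.

    Only the length is ever needed downstream: gaps in the output are filled
    with ``N`` characters, never with read bases.
    """

    id: str
    length: int


@dataclass
class RawAlignment:
    """One long-read-to-contig alignment in internal coordinates.

    ``[sr, er]`` is the aligned interval on the read (original orientation),
    ``[sc, ec]`` the aligned interval on the contig; ``strand`` is 1 for a
    forward alignment and 0 for reverse.
    """

    read_id: str
    contig_id: str
    sr: int
    er: int
    sc: int
    ec: int
    strand: int
    mapq: int


def read_contigs(path) -> ContigSet:
    """Parse a FASTA file of contigs.

    Sequences are uppercased; duplicate ids and empty sequences are rejected.
    An empty file yields an empty :class:`ContigSet`.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: expected FASTA header, got {line[:40]!r}"
                    )
                break
    contigs = ContigSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs.add(Contig(rec.id, str(rec.seq).upper()))
    return contigs


def _stored_query_interval(cigartuples) -> Tuple[int, int, int]:
    """Return (qstart, qend, full_length) on the stored (SEQ) orientation,
    counting hard clips as read bases."""
    leading = 0
    i = 0
    while i < len(cigartuples) and cigartuples[i][0] in _CLIP_OPS:
        leading += cigartuples[i][1]
        i += 1
    consumed = sum(n for op, n in cigartuples if op in _QUERY_OPS)
    total = sum(n for op, n in cigartuples if op in _QUERY_OPS or op in _CLIP_OPS)
    return leading, leading + consumed - 1, total


def read_alignments(path, contigs: ContigSet) -> Tuple[List[RawAlignment], Dict[str, LongReadInfo]]:
    """Read a SAM/BAM file of long reads aligned to contigs.

    Unmapped records are dropped; secondary and supplementary records are
    retained as candidate alignments (the reliability filter downstream
    removes low-MAPQ multi-mappers).  Coordinates are converted to the
    internal 0-based inclusive convention, with read coordinates on the
    read's original orientation.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    alignments: List[RawAlignment] = []
    reads: Dict[str, LongReadInfo] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped:
                continue
            rname = rec.reference_name
            if rname not in contigs:
                raise ValidationError(
                    f"alignment reference {rname!r} absent from contig set"
                )
            cig = rec.cigartuples
            if not cig:
                logger.warning("record %s has no CIGAR; skipped", rec.query_name)
                continue
            qstart, qend, read_len = _stored_query_interval(cig)
            if read_len <= 0 or qend < qstart:
                logger.warning(
                    "read length underivable for %s; skipped", rec.query_name
                )
                continue
            if rec.is_reverse:
                sr = read_len - 1 - qend
                er = read_len - 1 - qstart
            else:
                sr, er = qstart, qend
            sc = rec.reference_start
            ec = rec.reference_end - 1
            aln = RawAlignment(
                read_id=rec.query_name,
                contig_id=rname,
                sr=sr,
                er=er,
                sc=sc,
                ec=ec,
                strand=0 if rec.is_reverse else 1,
                mapq=rec.mapping_quality,
            )
            alignments.append(aln)
            prev = reads.get(rec.query_name)
            if prev is None or prev.length < read_len:
                reads[rec.query_name] = LongReadInfo(rec.query_name, read_len)
    return alignments, reads


def to_sam_coordinates(aln: RawAlignment, read_length: int) -> Tuple[int, int, int]:
    """Convert internal coordinates back to SAM convention.

    Returns ``(pos_1based, stored_qstart, stored_qend)`` where the query
    offsets are on the stored (possibly reverse-complemented) sequence.
    Inverse of the conversion applied by :func:`read_alignments`.
    """
    pos = aln.sc + 1
    if aln.strand == 0:
        qstart = read_length - 1 - aln.er
        qend = read_length - 1 - aln.sr
    else:
        qstart, qend = aln.sr, aln.er
    return pos, qstart, qend


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


LAYOUT_COLUMNS = ("scaffold_id", "index", "contig_id", "orientation", "gap_after", "offset")


def write_scaffolds(scaffolds, contigs: ContigSet, fasta_path, layout_path) -> None:
    """Render scaffolds to FASTA plus a machine-readable layout TSV.

    The sequence of a scaffold concatenates oriented contig sequences
    (reverse-complemented when orientation is 0) separated by
    ``max(round(gap), 1)`` ``N`` characters; the layout table preserves the
    signed, unclamped gap estimate.
    """
    with open(fasta_path, "w") as ff, open(layout_path, "w") as lf:
        lf.write("\t".join(LAYOUT_COLUMNS) + "\n")
        for scaf in scaffolds:
            pieces: List[str] = []
            offset = 0
            n_parts = len(scaf.parts)
            for idx, part in enumerate(scaf.parts):
                if part.contig_id not in contigs:
                    raise ValidationError(
                        f"scaffold {scaf.id}: unknown contig {part.contig_id!r}"
                    )
                seq = contigs[part.contig_id].sequence
                if part.orientation == 0:
                    seq = reverse_complement(seq)
                lf.write(
                    f"{scaf.id}\t{idx}\t{part.contig_id}\t"
                    f"{'+' if part.orientation == 1 else '-'}\t"
                    f"{part.gap_after:g}\t{offset}\n"
                )
                pieces.append(seq)
                offset += len(seq)
                if idx < n_parts - 1:
                    n_run = max(round(part.gap_after), 1)
                    pieces.append("N" * n_run)
                    offset += n_run
            ff.write(f">{scaf.id}\n{_wrap(''.join(pieces))}\n")
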