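import random

import pytest

from lrstitch.alignment_prep import RevisedAlignment, Thresholds, revise_alignment
from lrstitch.io_formats import Contig, ContigSet, LongReadInfo, RawAlignment
from lrstitch.local_scaffolding import LocalScaffold, LocalScaffoldEntry


@pytest.fixture
def thresholds():
    return Thresholds()


def make_contigs(lengths, seed=0):
    """ContigSet with pseudo-random sequences of the given lengths."""
    rng = random.Random(seed)
    cs = ContigSet()
    for cid, n in lengths.items():
        cs.add(Contig(cid, "".join(rng.choice("ACGT") for _ in range(n))))
    return cs


def make_raw(read_id="r1", contig_id="c1", sr=0, er=100, sc=0, ec=100, strand=1, mapq=60):
    return RawAlignment(read_id, contig_id, sr, er, sc, ec, strand, mapq)


def make_revised(read_len, contig_len, sr, er, sc, ec, strand=1, mapq=60, read_id="r1", contig_id="c1"):
    a = make_raw(read_id, contig_id, sr, er, sc, ec, strand, mapq)
    return revise_alignment(a, read_len, contig_len)


def make_ls(read_id, rows):
    """LocalScaffold from rows of (contig_id, orientation, gap_to_next, aln_len)."""
    return LocalScaffold(
        read_id=read_id,
        entries=[LocalScaffoldEntry(c, o, g, l) for c, o, g, l in rows],
    )


def check_revision_invariants(r, len_read, len_contig):
    """The eight revision invariants, stated in the alignment-colinear frame
    (reverse-strand read intervals are mirrored onto the stored orientation,
    where read and contig advance together)."""
    if r.strand == 1:
        csr, cer = r.sr, r.er
        csr_p, cer_p = r.sr_p, r.er_p
    else:
        csr, cer = len_read - 1 - r.er, len_read - 1 - r.sr
        csr_p, cer_p = len_read - 1 - r.er_p, len_read - 1 - r.sr_p
    assert csr_p <= csr
    assert r.sc_p <= r.sc
    assert cer_p >= cer
    assert r.ec_p >= r.ec
    assert min(csr_p, r.sc_p) == 0
    assert cer_p == len_read - 1 or r.ec_p == len_contig - 1
    assert csr - csr_p == r.sc - r.sc_p
    assert cer_p - cer == r.ec_p - r.ec


def random_valid_raw(rng, max_read=20000, max_contig=8000):
    """A random RawAlignment satisfying the interval invariants."""
    len_read = rng.randrange(200, max_read)
    len_contig = rng.randrange(150, max_contig)
    er = rng.randrange(1, len_read)
    sr = rng.randrange(0, er)
    ec = rng.randrange(1, len_contig)
    sc = rng.randrange(0, ec)
    return (
        make_raw(sr=sr, er=er, sc=sc, ec=ec, strand=rng.choice((0, 1)), mapq=rng.randrange(0, 61)),
        len_read,
        len_contig,
    )
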