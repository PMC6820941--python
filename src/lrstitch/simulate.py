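"""Synthetic genomes, fragmented contigs and noisy alignment records.

The generator emulates the inputs of the scaffolding pipeline directly at
the alignment level: a random genome is assembled from oriented contig
sequences separated by unassembled gap sequence, optionally with several
exact copies of a repeat unit; long reads are sampled from both strands with
a uniform length distribution; and for every contig interval a read overlaps
sufficiently, one SAM record is emitted with endpoints jittered by up to
``coord_noise`` bases and dropped with probability ``p_missing``.  Base-level
read error is abstracted as endpoint jitter, record dropout and MAPQ
degradation, because the algorithm under test consumes alignments, not
sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pysam

from .io_formats import Contig, ContigSet, LongReadInfo, reverse_complement

_ALPHABET = np.array(list("ACGT"))


@dataclass
class TruthLayout:
    """Ground-truth contig order, orientation and gaps along the genome."""

    placements: List[Tuple[str, int, int]] = field(default_factory=list)
    # (contig_id, orientation, gap_after); last gap is 0
    repeat_family: Dict[str, List[str]] = field(default_factory=dict)

    def adjacency_set(self) -> Set[Tuple[Tuple[str, int], Tuple[str, int]]]:
        """All oriented adjacencies, in both strand readings."""
        valid = set()
        for (ca, oa, _), (cb, ob, _) in zip(self.placements, self.placements[1:]):
            valid.add(((ca, oa), (cb, ob)))
            valid.add(((cb, 1 - ob), (ca, 1 - oa)))
        return valid


@dataclass
class SimulationConfig:
    genome_length: int = 100_000
    n_contigs: int = 20
    repeat_copies: int = 0
    repeat_unit_length: int = 2000
    repeat_standalone: bool = False
    read_length: Tuple[int, int] = (3000, 8000)
    coverage: float = 20.0
    coord_noise: int = 0
    p_missing: float = 0.0
    min_gap: int = 50
    max_gap: int = 200
    min_contig_length: int = 1500
    min_overlap: int = 101
    mapq_high: int = 60
    mapq_low_max: int = 20  # exclusive upper bound for degraded repeat MAPQ
    seed: int = 1

    def validate(self) -> None:
        if self.n_contigs < 1 or self.genome_length <= 0:
            raise ValueError("need a positive genome with at least one contig")
        if self.read_length[0] > self.read_length[1]:
            raise ValueError("read_length (min, max) out of order")


PRESETS: Dict[str, SimulationConfig] = {
    "clean": SimulationConfig(),
    "noisy": SimulationConfig(coord_noise=100, p_missing=0.1),
    "repeat": SimulationConfig(repeat_copies=3, repeat_unit_length=2000),
}


def preset_config(name: str, seed: int = 1) -> SimulationConfig:
    cfg = PRESETS[name]
    return SimulationConfig(**{**cfg.__dict__, "seed": seed})


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, n)])


def simulate_genome_and_contigs(
    cfg: SimulationConfig,
) -> Tuple[str, ContigSet, TruthLayout]:
    """Build a genome from oriented contigs, gaps and planted repeats.

    With ``repeat_standalone`` False (the default) the repeat is a single
    contig placed at ``repeat_copies`` genome positions — the collapsed
    representation an assembler produces for an exact repeat.  With it True,
    every copy is its own contig sharing one sequence.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_contigs
    n_gaps = n - 1 + (2 * cfg.repeat_copies if cfg.repeat_copies else 0)
    gap_budget = 0 if n_gaps == 0 else int(n_gaps * (cfg.min_gap + cfg.max_gap) / 2)
    contig_budget = cfg.genome_length - gap_budget - cfg.repeat_copies * cfg.repeat_unit_length
    avg = max(contig_budget // n, cfg.min_contig_length + 1)
    lo = cfg.min_contig_length
    hi = max(2 * avg - cfg.min_contig_length, lo + 2)
    lengths = rng.integers(lo, hi, n)

    contigs = ContigSet()
    placements: List[Tuple[str, int, int]] = []
    repeat_family: Dict[str, List[str]] = {}

    unique_ids = []
    for i in range(n):
        cid = f"contig_{i:03d}"
        seq = _random_seq(rng, int(lengths[i]))
        contigs.add(Contig(cid, seq))
        unique_ids.append(cid)

    repeat_slots: Set[int] = set()
    repeat_seq = ""
    repeat_ids: List[str] = []
    if cfg.repeat_copies:
        repeat_seq = _random_seq(rng, cfg.repeat_unit_length)
        # slots are junctions between consecutive unique contigs
        slots = rng.choice(n - 1, size=min(cfg.repeat_copies, n - 1), replace=False)
        repeat_slots = set(int(s) for s in slots)
        if cfg.repeat_standalone:
            repeat_ids = [f"repeat_{k:02d}" for k in range(len(repeat_slots))]
            for rid in repeat_ids:
                contigs.add(Contig(rid, repeat_seq))
        else:
            repeat_ids = ["repeat_00"]
            contigs.add(Contig("repeat_00", repeat_seq))
        repeat_family["repeat_unit_0"] = list(repeat_ids)

    genome_parts: List[str] = []
    copy_no = 0
    for i, cid in enumerate(unique_ids):
        orientation = int(rng.integers(0, 2))
        seq = contigs[cid].sequence
        genome_parts.append(seq if orientation == 1 else reverse_complement(seq))
        if i == n - 1 and i not in repeat_slots:
            placements.append((cid, orientation, 0))
            break
        gap = int(rng.integers(cfg.min_gap, cfg.max_gap + 1))
        placements.append((cid, orientation, gap))
        genome_parts.append(_random_seq(rng, gap))
        if i in repeat_slots:
            rid = repeat_ids[copy_no] if cfg.repeat_standalone else repeat_ids[0]
            copy_no += 1
            genome_parts.append(repeat_seq)
            gap2 = int(rng.integers(cfg.min_gap, cfg.max_gap + 1))
            last = i == n - 1
            placements.append((rid, 1, 0 if last else gap2))
            if not last:
                genome_parts.append(_random_seq(rng, gap2))
    genome = "".join(genome_parts)
    truth = TruthLayout(placements=placements, repeat_family=repeat_family)
    return genome, contigs, truth


@dataclass
class SimulatedAlignmentRecord:
    """Bookkeeping for one emitted SAM record, with pre-jitter coordinates."""

    read_id: str
    contig_id: str
    sr: int
    er: int
    sc: int
    ec: int
    true_sr: int
    true_er: int
    true_sc: int
    true_ec: int
    strand: int
    mapq: int


def _genome_intervals(truth: TruthLayout, contigs: ContigSet) -> List[Tuple[str, int, int, int]]:
    """(contig_id, orientation, genome_start, genome_end) per placement."""
    out = []
    pos = 0
    for cid, ori, gap in truth.placements:
        length = contigs.length(cid)
        out.append((cid, ori, pos, pos + length - 1))
        pos += length + gap
    return out


def simulate_alignments(
    genome: str,
    contigs: ContigSet,
    truth: TruthLayout,
    cfg: SimulationConfig,
    sam_path,
) -> Tuple[List[SimulatedAlignmentRecord], Dict[str, LongReadInfo]]:
    """Sample reads and write their per-contig alignment records as SAM.

    Records carry no sequence; the CIGAR (clips around a match, with a
    mid-alignment indel absorbing any jitter-induced span difference) encodes
    the coordinates, so read lengths are derivable downstream.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    glen = len(genome)
    lmin, lmax = cfg.read_length
    lmin = min(lmin, glen)
    lmax = min(lmax, glen)
    mean_len = (lmin + lmax) / 2
    n_reads = 0 if cfg.coverage <= 0 else math.ceil(cfg.coverage * glen / mean_len)
    intervals = _genome_intervals(truth, contigs)
    standalone_groups: Dict[str, List[str]] = {}
    if cfg.repeat_standalone:
        for fam in truth.repeat_family.values():
            for cid in fam:
                standalone_groups[cid] = fam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": cid, "LN": contigs.length(cid)} for cid in contigs.ids()],
    }
    ref_index = {cid: k for k, cid in enumerate(contigs.ids())}
    records: List[SimulatedAlignmentRecord] = []
    reads: Dict[str, LongReadInfo] = {}

    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for k in range(n_reads):
            rlen = int(rng.integers(lmin, lmax + 1))
            start = int(rng.integers(0, glen - rlen + 1))
            end = start + rlen - 1
            read_strand = int(rng.integers(0, 2))
            rid = f"read_{k:05d}"
            reads[rid] = LongReadInfo(rid, rlen)
            for cid, ori, gstart, gend in intervals:
                a = max(start, gstart)
                b = min(end, gend)
                if b - a + 1 < cfg.min_overlap:
                    continue
                if cfg.p_missing > 0 and rng.random() < cfg.p_missing:
                    continue
                target = cid
                mapq = cfg.mapq_high
                if cid in standalone_groups:
                    group = standalone_groups[cid]
                    target = group[int(rng.integers(0, len(group)))]
                    mapq = int(rng.integers(0, cfg.mapq_low_max))
                if ori == 1:
                    sc, ec = a - gstart, b - gstart
                else:
                    sc, ec = gend - b, gend - a
                if read_strand == 1:
                    sr, er = a - start, b - start
                else:
                    sr, er = end - b, end - a
                fwd_aln = 1 if read_strand == ori else 0
                true_sr, true_er, true_sc, true_ec = sr, er, sc, ec
                if cfg.coord_noise:
                    clen = contigs.length(target)
                    jit = rng.integers(-cfg.coord_noise, cfg.coord_noise + 1, 4)
                    sr = int(np.clip(sr + jit[0], 0, rlen - 1))
                    er = int(np.clip(er + jit[1], 0, rlen - 1))
                    sc = int(np.clip(sc + jit[2], 0, clen - 1))
                    ec = int(np.clip(ec + jit[3], 0, clen - 1))
                    if er <= sr or ec <= sc:
                        continue  # degenerate after jitter: treated as dropout
                rec = SimulatedAlignmentRecord(
                    read_id=rid,
                    contig_id=target,
                    sr=sr,
                    er=er,
                    sc=sc,
                    ec=ec,
                    true_sr=true_sr,
                    true_er=true_er,
                    true_sc=true_sc,
                    true_ec=true_ec,
                    strand=fwd_aln,
                    mapq=mapq,
                )
                records.append(rec)
                out.write(_to_segment(rec, rlen, header, ref_index))
    return records, reads


def _to_segment(rec: SimulatedAlignmentRecord, rlen: int, header, ref_index) -> pysam.AlignedSegment:
    if rec.strand == 1:
        qstart, qend = rec.sr, rec.er
    else:
        qstart, qend = rlen - 1 - rec.er, rlen - 1 - rec.sr
    qspan = qend - qstart + 1
    rspan = rec.ec - rec.sc + 1
    m = min(qspan, rspan)
    m1, m2 = m // 2, m - m // 2
    ops = []
    if qstart:
        ops.append(f"{qstart}S")
    if qspan == rspan:
        ops.append(f"{m}M")
    elif qspan > rspan:
        ops.append(f"{m1}M{qspan - rspan}I{m2}M")
    else:
        ops.append(f"{m1}M{rspan - qspan}D{m2}M")
    trail = rlen - 1 - qend
    if trail:
        ops.append(f"{trail}S")
    seg = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(header))
    seg.query_name = rec.read_id
    seg.flag = 16 if rec.strand == 0 else 0
    seg.reference_id = ref_index[rec.contig_id]
    seg.reference_start = rec.sc
    seg.mapping_quality = rec.mapq
    seg.cigarstring = "".join(ops)
    return seg


def write_truth(truth: TruthLayout, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\torientation\tgap_after\n")
        for cid, ori, gap in truth.placements:
            fh.write(f"{cid}\t{ori}\t{gap}\n")


def read_truth(path) -> TruthLayout:
    placements = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            cid, ori, gap = line.rstrip("\n").split("\t")
            placements.append((cid, int(ori), int(gap)))
    return TruthLayout(placements=placements)


def write_read_info(reads: Dict[str, LongReadInfo], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlength\n")
        for rid in sorted(reads):
            fh.write(f"{rid}\t{reads[rid].length}\n")


def write_contigs_fasta(contigs: ContigSet, path) -> None:
    with open(path, "w") as fh:
        for cid in contigs.ids():
            seq = contigs[cid].sequence
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def simulate_dataset(cfg: SimulationConfig, out_dir) -> Dict[str, str]:
    """Write contigs.fa, alignments.sam, reads.info.tsv and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, contigs, truth = simulate_genome_and_contigs(cfg)
    paths = {
        "contigs": str(out / "contigs.fa"),
        "alignments": str(out / "alignments.sam"),
        "reads": str(out / "reads.info.tsv"),
        "truth": str(out / "truth.tsv"),
    }
    write_contigs_fasta(contigs, paths["contigs"])
    _, reads = simulate_alignments(genome, contigs, truth, cfg, paths["alignments"])
    write_read_info(reads, paths["reads"])
    write_truth(truth, paths["truth"])
    return paths


def count_truth_violations(scaffolds, truth: TruthLayout) -> int:
    """Junctions in the scaffolds that are not adjacencies of the truth
    layout (order or orientation wrong), summed over scaffolds."""
    valid = truth.adjacency_set()
    violations = 0
    for s in scaffolds:
        for u, v in zip(s.parts, s.parts[1:]):
            if ((u.contig_id, u.orientation), (v.contig_id, v.orientation)) not in valid:
                violations += 1
    return violations


def matches_truth_exactly(scaffolds, truth: TruthLayout) -> bool:
    """True when a single scaffold reproduces the truth layout's contig
    order and orientations, up to whole-scaffold reversal."""
    if len(scaffolds) != 1:
        return False
    sig = scaffolds[0].signature()
    truth_sig = tuple((cid, ori) for cid, ori, _ in truth.placements)
    rev_sig = tuple((cid, 1 - ori) for cid, ori in reversed(truth_sig))
    return sig == truth_sig or sig == rev_sig
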