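"""Truth-labelled synthetic genomes and long-read alignments.

The simulator stands in for a read simulator plus aligner so that the
whole calling pipeline can be exercised without external data.  It

1. draws a random reference genome,
2. implants non-overlapping SVs of the five classes into one or two
   donor haplotypes, keeping a block map from donor to reference
   coordinates, and
3. tiles the donor with long reads and emits, for every read, the SAM
   records an idealized aligner would produce: CIGAR D/I runs for
   deletions and insertions, split supplementary records with correct
   strands for inversions, tandem and interspersed duplications.

In *noisy* mode, indel-dominated sequencing errors (1-bp I/D runs at a
configurable rate, insertion-heavy as in raw PacBio reads) are scattered
through every aligned block; block boundaries stay exact, which mimics
an aligner that recovers the true breakpoints from error-bearing reads.

Read lengths are log-normal with an 8 kb median, truncated to
[500 bp, 50 kb].  Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from svclique.model import TruthVariant

DEFAULT_SIZE_RANGE = (50, 10_000)
DEFAULT_COUNTS = {
    "deletion": 200,
    "inversion": 100,
    "tandem_duplication": 100,
    "interspersed_duplication": 200,
    "novel_insertion": 0,
}
READ_LENGTH_MEDIAN = 8_000
READ_LENGTH_SIGMA = 0.45
READ_LENGTH_MIN = 500
READ_LENGTH_MAX = 50_000
#: aligned pieces shorter than this are left unaligned (soft-clipped)
MIN_SEGMENT_QUERY_LEN = 30
#: donor-to-reference forward jumps below this stay within one segment
SEGMENT_SPLIT_DISTANCE = 10_000
#: min separation between implanted variants (and duplication origins)
PLACEMENT_MARGIN = 300
#: min distance between a duplication's origin and its destination
ORIGIN_MIN_DISTANCE = 20_000

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_reference(
    n_chroms: int, length_bp: int, seed: int
) -> Dict[str, str]:
    """Random i.i.d. uniform A/C/G/T genome, reproducible per seed."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if n_chroms <= 0:
        raise ValueError("n_chroms must be positive")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {
        f"chr{i + 1}": b"".join(
            bases[rng.integers(0, 4, size=length_bp)]
        ).decode()
        for i in range(n_chroms)
    }


@dataclass
class Block:
    """One donor-genome block.

    kind 'M': donor carries reference ``chrom[ref_start:ref_end]``
    (reverse-complemented when strand is '-').  kind 'I': donor carries
    ``seq`` with no reference counterpart.
    """

    kind: str  # 'M' or 'I'
    chrom: str = ""
    ref_start: int = 0
    ref_end: int = 0
    strand: str = "+"
    seq: str = ""

    def length(self) -> int:
        return len(self.seq) if self.kind == "I" else self.ref_end - self.ref_start


@dataclass
class SimulatedGenome:
    """Reference plus donor haplotypes and their truth annotation."""

    reference: Dict[str, str]
    truth: List[TruthVariant]
    # per haplotype: {chrom: [Block, ...]}
    haplotypes: List[Dict[str, List[Block]]] = field(default_factory=list)

    def donor_sequence(self, hap: int = 0) -> Dict[str, str]:
        out = {}
        for chrom, blocks in self.haplotypes[hap].items():
            parts = []
            for blk in blocks:
                if blk.kind == "I":
                    parts.append(blk.seq)
                else:
                    s = self.reference[blk.chrom][blk.ref_start:blk.ref_end]
                    parts.append(revcomp(s) if blk.strand == "-" else s)
            out[chrom] = "".join(parts)
        return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return b"".join(bases[rng.integers(0, 4, size=length)]).decode()


def _place(
    rng: np.random.Generator,
    occupied: Dict[str, List[Tuple[int, int]]],
    chrom_lengths: Dict[str, int],
    size: int,
    margin: int = PLACEMENT_MARGIN,
    max_tries: int = 1000,
    away_from: Optional[Tuple[str, int]] = None,
) -> Tuple[str, int]:
    """Find a start for an interval of ``size`` bp clear of existing ones."""
    chroms = sorted(chrom_lengths)
    for _ in range(max_tries):
        chrom = chroms[rng.integers(0, len(chroms))]
        limit = chrom_lengths[chrom] - size - margin
        if limit <= margin:
            continue
        start = int(rng.integers(margin, limit))
        if away_from is not None and chrom == away_from[0]:
            if abs(start - away_from[1]) < ORIGIN_MIN_DISTANCE:
                continue
        lo, hi = start - margin, start + size + margin
        if any(b < hi and lo < e for b, e in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append((start, start + size))
        return chrom, start
    raise RuntimeError("could not place variant: genome too crowded")


def implant_variants(
    reference: Dict[str, str],
    counts: Dict[str, int],
    size_range: Tuple[int, int] = DEFAULT_SIZE_RANGE,
    zygosity: str = "hom",
    seed: int = 0,
) -> SimulatedGenome:
    """Implant non-overlapping SVs into the reference.

    ``counts`` maps SV class to the number of variants.  With zygosity
    'hom' one donor haplotype carries every variant and both simulated
    haplotypes are identical; with 'het' the second haplotype is the
    unmodified reference, so half of the reads sampled later carry no
    variant.  Interspersed-duplication origins are placed at least 20 kb
    from their destination and never overlap another variant.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = {c: len(s) for c, s in reference.items()}
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad size range {size_range}")

    plan = []
    for sv_class in sorted(counts):
        for _ in range(counts[sv_class]):
            plan.append((sv_class, int(rng.integers(lo, hi + 1))))
    rng.shuffle(plan)

    truth: List[TruthVariant] = []
    for sv_class, size in plan:
        if sv_class in ("interspersed_duplication", "novel_insertion"):
            # destination is a point; reserve a small footprint around it
            chrom, start = _place(rng, occupied, chrom_lengths, 1)
            origin = None
            if sv_class == "interspersed_duplication":
                oc, ob = _place(
                    rng, occupied, chrom_lengths, size, away_from=(chrom, start)
                )
                origin = (oc, ob, ob + size)
            truth.append(
                TruthVariant(
                    sv_class, chrom, start, start + size, size, zygosity, origin
                )
            )
        else:
            chrom, start = _place(rng, occupied, chrom_lengths, size)
            truth.append(
                TruthVariant(sv_class, chrom, start, start + size, size, zygosity)
            )
    truth.sort(key=lambda t: (t.chrom, t.begin))

    donor_hap = _build_haplotype(reference, truth, rng)
    ref_hap = {
        chrom: [Block("M", chrom, 0, length, "+")]
        for chrom, length in chrom_lengths.items()
    }
    haplotypes = [donor_hap, donor_hap if zygosity == "hom" else ref_hap]
    return SimulatedGenome(reference, truth, haplotypes)


def _build_haplotype(
    reference: Dict[str, str],
    truth: Sequence[TruthVariant],
    rng: np.random.Generator,
) -> Dict[str, List[Block]]:
    by_chrom: Dict[str, List[TruthVariant]] = {c: [] for c in reference}
    for t in truth:
        by_chrom[t.chrom].append(t)
    hap: Dict[str, List[Block]] = {}
    for chrom, seq in reference.items():
        cursor = 0
        blocks: List[Block] = []

        def advance(to: int) -> None:
            nonlocal cursor
            if to > cursor:
                blocks.append(Block("M", chrom, cursor, to, "+"))
            cursor = to

        for t in sorted(by_chrom[chrom], key=lambda t: t.begin):
            if t.sv_class == "deletion":
                advance(t.begin)
                cursor = t.end
            elif t.sv_class == "inversion":
                advance(t.begin)
                blocks.append(Block("M", chrom, t.begin, t.end, "-"))
                cursor = t.end
            elif t.sv_class == "tandem_duplication":
                advance(t.end)
                blocks.append(Block("M", chrom, t.begin, t.end, "+"))
            elif t.sv_class == "interspersed_duplication":
                advance(t.begin)
                oc, ob, oe = t.origin
                blocks.append(Block("M", oc, ob, oe, "+"))
            elif t.sv_class == "novel_insertion":
                advance(t.begin)
                blocks.append(Block("I", seq=_random_seq(rng, t.length)))
        advance(len(seq))
        hap[chrom] = blocks
    return hap


# ---------------------------------------------------------------------------
# alignment synthesis


@dataclass
class _Piece:
    """Part of one read overlapping one donor block."""

    kind: str  # 'M' or 'I'
    chrom: str = ""
    ref_start: int = 0
    ref_end: int = 0
    strand: str = "+"
    seq: str = ""


@dataclass
class _Segment:
    chrom: str
    strand: str
    ref_start: int
    ref_end: int
    ops: List[Tuple[str, int]]
    read_start: int
    read_end: int


def _read_pieces(
    blocks: List[Block],
    offsets: List[int],
    reference: Dict[str, str],
    a: int,
    b: int,
) -> List[_Piece]:
    """Pieces of the read covering donor interval [a, b)."""
    pieces = []
    for blk, off in zip(blocks, offsets):
        blk_len = blk.length()
        lo, hi = max(a, off), min(b, off + blk_len)
        if lo >= hi:
            continue
        s, t = lo - off, hi - off  # sub-interval within the block
        if blk.kind == "I":
            pieces.append(_Piece("I", seq=blk.seq[s:t]))
        elif blk.strand == "+":
            rs, re = blk.ref_start + s, blk.ref_start + t
            pieces.append(
                _Piece("M", blk.chrom, rs, re, "+", reference[blk.chrom][rs:re])
            )
        else:
            rs, re = blk.ref_end - t, blk.ref_end - s
            pieces.append(
                _Piece(
                    "M", blk.chrom, rs, re, "-",
                    revcomp(reference[blk.chrom][rs:re]),
                )
            )
    return pieces


def _noisy_ops(
    ref_len: int,
    seq: str,
    rng: np.random.Generator,
    ins_rate: float,
    del_rate: float,
) -> Tuple[List[Tuple[str, int]], str]:
    """Scatter 1-bp indel errors through an M run of ``ref_len`` bases.

    The reference span is preserved exactly (deleted read bases become
    D ops inside the run), so downstream breakpoints do not drift.
    """
    n_del = rng.binomial(ref_len, del_rate)
    n_ins = rng.binomial(ref_len, ins_rate)
    if n_del + n_ins == 0:
        return [("M", ref_len)], seq
    del_pos = set(rng.choice(ref_len, size=min(n_del, ref_len), replace=False).tolist())
    ins_pos: Dict[int, int] = {}
    for p in rng.integers(0, ref_len, size=n_ins).tolist():
        ins_pos[p] = ins_pos.get(p, 0) + 1
    ops: List[Tuple[str, int]] = []
    out_seq: List[str] = []

    def push(op: str, length: int) -> None:
        if length <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    run = 0
    for i in range(ref_len):
        if i in ins_pos:
            push("M", run)
            run = 0
            k = ins_pos[i]
            push("I", k)
            out_seq.append(_random_seq(rng, k))
        if i in del_pos:
            push("M", run)
            run = 0
            push("D", 1)
        else:
            run += 1
            out_seq.append(seq[i])
    push("M", run)
    return ops, "".join(out_seq)


def _segments_from_pieces(
    pieces: List[_Piece],
    rng: np.random.Generator,
    noisy: bool,
    ins_rate: float,
    del_rate: float,
) -> Tuple[List[_Segment], str]:
    """Group read pieces into alignment segments; returns (segments, read seq).

    Consecutive forward-strand pieces on one chromosome whose reference
    coordinates advance by less than SEGMENT_SPLIT_DISTANCE stay in one
    segment (the gap becomes a D run); insertion pieces between them
    become I runs.  Any other transition starts a new segment, which is
    how split alignments around inversions and duplications arise.
    """
    segments: List[_Segment] = []
    seq_parts: List[str] = []
    qpos = 0
    cur: Optional[_Segment] = None
    pending_ins = 0

    for piece in pieces:
        if piece.kind == "I":
            seq_parts.append(piece.seq)
            qpos += len(piece.seq)
            pending_ins += len(piece.seq)
            continue
        ops, pseq = (
            _noisy_ops(piece.ref_end - piece.ref_start, piece.seq, rng,
                       ins_rate, del_rate)
            if noisy
            else ([("M", piece.ref_end - piece.ref_start)], piece.seq)
        )
        qlen = len(pseq)
        colinear = (
            cur is not None
            and cur.chrom == piece.chrom
            and cur.strand == piece.strand == "+"
            and 0 <= piece.ref_start - cur.ref_end < SEGMENT_SPLIT_DISTANCE
        )
        if colinear:
            if pending_ins:
                cur.ops.append(("I", pending_ins))
            gap = piece.ref_start - cur.ref_end
            if gap:
                cur.ops.append(("D", gap))
            cur.ops.extend(ops)
            cur.ref_end = piece.ref_end
            cur.read_end = qpos + qlen
        else:
            if cur is not None:
                segments.append(cur)
            cur = _Segment(
                piece.chrom, piece.strand, piece.ref_start, piece.ref_end,
                list(ops), qpos, qpos + qlen,
            )
        seq_parts.append(pseq)
        qpos += qlen
        pending_ins = 0
    if cur is not None:
        segments.append(cur)
    segments = [
        s for s in segments if s.read_end - s.read_start >= MIN_SEGMENT_QUERY_LEN
    ]
    return segments, "".join(seq_parts)


def _merge_ops(ops: List[Tuple[str, int]]) -> List[Tuple[str, int]]:
    out: List[Tuple[str, int]] = []
    for op, length in ops:
        if length <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + length)
        else:
            out.append((op, length))
    return out


def _draw_read_length(rng: np.random.Generator) -> int:
    length = int(rng.lognormal(math.log(READ_LENGTH_MEDIAN), READ_LENGTH_SIGMA))
    return max(READ_LENGTH_MIN, min(READ_LENGTH_MAX, length))


def synthesize_alignments(
    sim: SimulatedGenome,
    coverage: float,
    out_sam: Union[str, Path],
    mode: str = "idealized",
    seed: int = 0,
    ins_rate: float = 0.06,
    del_rate: float = 0.03,
) -> Path:
    """Tile the donor haplotypes with reads and write a sorted SAM file.

    Each read is emitted as the records an idealized aligner would
    produce for it; the longest segment is the primary record, the rest
    are supplementary.  ``mode`` is 'idealized' or 'noisy'.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if mode not in ("idealized", "noisy"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    noisy = mode == "noisy"

    hap_meta = []  # (hap_index, chrom, blocks, offsets, donor_len)
    for h, hap in enumerate(sim.haplotypes):
        for chrom in sorted(hap):
            blocks = hap[chrom]
            offsets, pos = [], 0
            for blk in blocks:
                offsets.append(pos)
                pos += blk.length()
            hap_meta.append((h, chrom, blocks, offsets, pos))

    mean_hap_len = sum(m[4] for m in hap_meta) / max(1, len(sim.haplotypes))
    target_bases = coverage * mean_hap_len

    records = []  # (chrom, pos, pysam-ready dict)
    total = 0
    read_idx = 0
    while total < target_bases:
        h, chrom, blocks, offsets, donor_len = hap_meta[
            rng.integers(0, len(hap_meta))
        ]
        length = min(_draw_read_length(rng), donor_len)
        start = int(rng.integers(0, donor_len - length + 1))
        pieces = _read_pieces(blocks, offsets, sim.reference, start, start + length)
        segments, read_seq = _segments_from_pieces(
            pieces, rng, noisy, ins_rate, del_rate
        )
        read_idx += 1
        total += length
        if not segments:
            continue
        name = f"read_{read_idx}"
        primary = max(range(len(segments)), key=lambda i: (
            segments[i].read_end - segments[i].read_start, -i))
        for i, seg in enumerate(segments):
            records.append(
                _sam_record(name, seg, read_seq, is_supplementary=(i != primary))
            )

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": len(s)} for c, s in sorted(sim.reference.items())
        ],
    }
    chrom_order = {c: i for i, c in enumerate(sorted(sim.reference))}
    records.sort(key=lambda r: (chrom_order[r["chrom"]], r["pos"], r["name"]))
    out_sam = Path(out_sam)
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as af:
        for rec in records:
            a = pysam.AlignedSegment(af.header)
            a.query_name = rec["name"]
            a.flag = rec["flag"]
            a.reference_id = af.header.get_tid(rec["chrom"])
            a.reference_start = rec["pos"]
            a.mapping_quality = 60
            a.cigarstring = rec["cigar"]
            a.query_sequence = rec["seq"]
            af.write(a)
    return out_sam


def _sam_record(name, seg: _Segment, read_seq: str, is_supplementary: bool):
    read_len = len(read_seq)
    pre = seg.read_start
    post = read_len - seg.read_end
    ops = list(seg.ops)
    seq = read_seq
    if seg.strand == "-":
        ops = ops[::-1]
        pre, post = post, pre
        seq = revcomp(read_seq)
    cigar_ops = _merge_ops([("S", pre)] + ops + [("S", post)])
    flag = 0
    if seg.strand == "-":
        flag |= 0x10
    if is_supplementary:
        flag |= 0x800
    return {
        "name": name,
        "chrom": seg.chrom,
        "pos": seg.ref_start,
        "flag": flag,
        "cigar": "".join(f"{l}{op}" for op, l in cigar_ops),
        "seq": seq,
    }


# ---------------------------------------------------------------------------
# file output


def write_fasta(genome: Dict[str, str], path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    return path


def write_truth_bed(truth: Sequence[TruthVariant], path: Union[str, Path]) -> Path:
    """Truth records: chrom, start, end, class, origin (or '.')."""
    path = Path(path)
    with open(path, "w") as fh:
        for t in sorted(truth, key=lambda t: (t.chrom, t.begin)):
            origin = f"{t.origin[0]}:{t.origin[1]}-{t.origin[2]}" if t.origin else "."
            fh.write(
                f"{t.chrom}\t{t.begin}\t{t.end}\t{t.sv_class}\t{origin}\t{t.zygosity}\n"
            )
    return path


def read_truth_bed(path: Union[str, Path]) -> List[TruthVariant]:
    truth = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, b, e, sv_class, origin_s, zyg = line.rstrip("\n").split("\t")
            origin = None
            if origin_s != ".":
                oc, rest = origin_s.split(":")
                ob, oe = rest.split("-")
                origin = (oc, int(ob), int(oe))
            b, e = int(b), int(e)
            truth.append(TruthVariant(sv_class, chrom, b, e, e - b, zyg, origin))
    return truth
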