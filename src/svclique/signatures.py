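"""COLLECT stage: extract SV signatures from individual reads.

Two kinds of evidence are used.  *Intra-alignment* signatures are large
deletion (D) or insertion (I) runs in a single record's CIGAR string.
*Inter-alignment* signatures come from the relative placement and
orientation of a read's split-alignment segments: reference gaps not
covered by read sequence (DEL), read sequence not covered by reference
(INS), backward reference jumps (TAN), strand-flipped middle segments
(INV), middle segments transplanted from elsewhere (DUP with origin), and
junctions between distant loci (BRK pairs).

The split-alignment rules are heuristics; their tolerances are module
constants below and are exposed through :func:`collect_signatures`.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Tuple

from svclique.model import AlignmentSegment, Signature

logger = logging.getLogger(__name__)

DEFAULT_MIN_SV_SIZE = 50
#: matched bases allowed between two CIGAR gaps merged into one event
GAP_MERGE_TOLERANCE = 10
#: max reference gap between flanks still called "adjacent" (DUP rule)
SEGMENT_GAP_TOLERANCE = 100
#: min reference distance for a locus to count as "elsewhere"/"distant"
MIN_DISTANCE = 10_000
#: reads with more segments are likely mapping artifacts and are skipped
MAX_SEGMENTS_PER_READ = 10

_REF_CONSUMING = frozenset("MDN=X")


def extract_intra_signatures(
    segment: AlignmentSegment,
    min_sv_size: int = DEFAULT_MIN_SV_SIZE,
    gap_merge_tolerance: int = GAP_MERGE_TOLERANCE,
) -> List[Signature]:
    """Deletion and insertion signatures from one record's CIGAR string.

    Same-type gaps separated by at most ``gap_merge_tolerance`` aligned
    reference bases are merged into a single event before the size filter,
    because sequencing errors tend to shatter one long gap into several
    adjacent runs.
    """
    dels: List[Tuple[int, int]] = []  # (ref_begin, ref_end)
    inss: List[Tuple[int, int]] = []  # (ref_anchor, inserted_length)
    ref = segment.ref_start
    for op, length in segment.cigar:
        if op == "D":
            dels.append((ref, ref + length))
        elif op == "I":
            inss.append((ref, length))
        if op in _REF_CONSUMING:
            ref += length

    merged_dels: List[Tuple[int, int]] = []
    for b, e in dels:
        if merged_dels and b - merged_dels[-1][1] <= gap_merge_tolerance:
            merged_dels[-1] = (merged_dels[-1][0], e)
        else:
            merged_dels.append((b, e))
    merged_inss: List[Tuple[int, int]] = []
    for a, length in inss:
        if merged_inss and a - merged_inss[-1][0] <= gap_merge_tolerance:
            merged_inss[-1] = (merged_inss[-1][0], merged_inss[-1][1] + length)
        else:
            merged_inss.append((a, length))

    out: List[Signature] = []
    for b, e in merged_dels:
        if e - b >= min_sv_size:
            out.append(
                Signature("DEL", segment.chrom, b, e, "intra", segment.read_name)
            )
    for a, length in merged_inss:
        if length >= min_sv_size:
            out.append(
                Signature(
                    "INS", segment.chrom, a, a + length, "intra", segment.read_name
                )
            )
    out.sort(key=lambda s: s.begin)
    return out


def _junction(left: AlignmentSegment, right: AlignmentSegment) -> Tuple[int, int]:
    """Reference coordinates facing the junction of two read-adjacent
    segments on the same strand: (end of left in read order, start of
    right in read order)."""
    if left.strand == "+":
        return left.ref_end, right.ref_start
    return left.ref_start, right.ref_end


def _pair_signatures(
    prev: AlignmentSegment,
    nxt: AlignmentSegment,
    min_sv_size: int,
    min_distance: int,
) -> List[Signature]:
    """Apply the adjacent-pair rules (DEL / INS / TAN / BRK)."""
    read_gap = nxt.read_start - prev.read_end
    name = prev.read_name

    if prev.chrom == nxt.chrom and prev.strand == nxt.strand:
        jl, jr = _junction(prev, nxt)
        ref_gap = jr - jl if prev.strand == "+" else jl - jr
        if prev.strand == "-":
            jl, jr = jr, jl  # jl is now the lower coordinate of the junction
        if -min_distance < ref_gap <= -min_sv_size:
            # backward reference jump: the read traverses this interval twice
            lo, hi = sorted((jl, jr))
            return [Signature("TAN", prev.chrom, lo, hi, "inter", name)]
        if -min_sv_size < ref_gap < min_distance:
            if ref_gap - read_gap >= min_sv_size:
                lo, hi = sorted((jl, jr))
                return [Signature("DEL", prev.chrom, lo, hi, "inter", name)]
            if read_gap - ref_gap >= min_sv_size:
                ins_len = read_gap - max(ref_gap, 0)
                anchor = min(jl, jr)
                return [
                    Signature(
                        "INS", prev.chrom, anchor, anchor + ins_len, "inter", name
                    )
                ]
            return []

    # distant loci, strand flip, or chromosome change: one breakend per side
    prev_pos = prev.ref_end if prev.strand == "+" else prev.ref_start
    nxt_pos = nxt.ref_start if nxt.strand == "+" else nxt.ref_end
    return [
        Signature(
            "BRK", prev.chrom, prev_pos, prev_pos, "inter", name,
            mate=(nxt.chrom, nxt_pos),
        ),
        Signature(
            "BRK", nxt.chrom, nxt_pos, nxt_pos, "inter", name,
            mate=(prev.chrom, prev_pos),
        ),
    ]


def _triple_signature(
    a: AlignmentSegment,
    b: AlignmentSegment,
    c: AlignmentSegment,
    min_distance: int,
    segment_gap_tolerance: int,
) -> Optional[Signature]:
    """Apply the consecutive-triple rules (INV / DUP with origin)."""
    name = a.read_name
    # inversion: strand-flipped middle segment lying between the flanks
    if (
        a.chrom == b.chrom == c.chrom
        and a.strand == c.strand != b.strand
    ):
        if a.strand == "+":
            between = a.ref_end - segment_gap_tolerance <= b.ref_start and \
                b.ref_end <= c.ref_start + segment_gap_tolerance
        else:
            between = c.ref_end - segment_gap_tolerance <= b.ref_start and \
                b.ref_end <= a.ref_start + segment_gap_tolerance
        if between:
            return Signature("INV", b.chrom, b.ref_start, b.ref_end, "inter", name)

    # transplanted middle segment: flanks reference-adjacent, middle elsewhere
    if a.chrom == c.chrom and a.strand == c.strand:
        jl, jr = _junction(a, c)
        gap = jr - jl if a.strand == "+" else jl - jr
        if abs(gap) < segment_gap_tolerance:
            junction = min(jl, jr)
            elsewhere = b.chrom != a.chrom or (
                min(abs(b.ref_start - junction), abs(b.ref_end - junction))
                >= min_distance
            )
            if elsewhere:
                origin_len = b.ref_end - b.ref_start
                return Signature(
                    "DUP",
                    a.chrom,
                    junction,
                    junction + origin_len,
                    "inter",
                    name,
                    origin=(b.chrom, b.ref_start, b.ref_end),
                )
    return None


def extract_inter_signatures(
    segments: List[AlignmentSegment],
    min_sv_size: int = DEFAULT_MIN_SV_SIZE,
    segment_gap_tolerance: int = SEGMENT_GAP_TOLERANCE,
    min_distance: int = MIN_DISTANCE,
) -> List[Signature]:
    """Signatures from the split-alignment geometry of one read.

    ``segments`` must all belong to one read and be sorted by read_start.
    Consecutive triples are examined first (inversion and transplanted-
    segment rules); pairs consumed by a firing triple are excluded from
    the pairwise rules.
    """
    if len(segments) < 2:
        return []
    out: List[Signature] = []
    consumed_pairs = set()
    for i in range(len(segments) - 2):
        sig = _triple_signature(
            segments[i], segments[i + 1], segments[i + 2],
            min_distance, segment_gap_tolerance,
        )
        if sig is not None:
            out.append(sig)
            consumed_pairs.update({i, i + 1})
    for i in range(len(segments) - 1):
        if i in consumed_pairs:
            continue
        out.extend(
            _pair_signatures(segments[i], segments[i + 1], min_sv_size, min_distance)
        )
    return out


def collect_signatures(
    grouped: Dict[str, List[AlignmentSegment]],
    min_sv_size: int = DEFAULT_MIN_SV_SIZE,
    gap_merge_tolerance: int = GAP_MERGE_TOLERANCE,
    segment_gap_tolerance: int = SEGMENT_GAP_TOLERANCE,
    min_distance: int = MIN_DISTANCE,
    max_segments: int = MAX_SEGMENTS_PER_READ,
) -> List[Signature]:
    """All signatures from all reads, in deterministic order.

    Reads split into more than ``max_segments`` pieces are skipped as
    likely mapping artifacts.
    """
    out: List[Signature] = []
    for read_name in sorted(grouped):
        segs = grouped[read_name]
        if len(segs) > max_segments:
            logger.warning(
                "read %s has %d segments (> %d); skipped",
                read_name, len(segs), max_segments,
            )
            continue
        for seg in segs:
            out.extend(
                extract_intra_signatures(seg, min_sv_size, gap_merge_tolerance)
            )
        out.extend(
            extract_inter_signatures(
                segs, min_sv_size, segment_gap_tolerance, min_distance
            )
        )
    out.sort(key=lambda s: (s.chrom, s.begin, s.read_name, s.sig_type))
    return out
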