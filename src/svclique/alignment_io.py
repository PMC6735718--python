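"""SAM/BAM input: per-record parsing and per-read grouping.

Secondary (0x100) and unmapped (0x4) records are skipped; supplementary
records (0x800) are kept because they carry the split-alignment geometry
that inter-alignment signatures are built from.  Hard clips are treated
like soft clips when reconstructing read coordinates, since supplementary
records commonly hard-clip the parts of the read aligned elsewhere.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, Iterable, Iterator, List

import pysam

from svclique.model import AlignmentSegment

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 20

_CIGAR_OPS = "MIDNSHP=XB"
_QUERY_CONSUMING = frozenset("MIS=X")
_CLIP_OPS = frozenset("SH")


def _read_coordinates(cigar, is_reverse: bool):
    """Read-space interval of the aligned part, on the original read.

    Clip lengths at either end of the CIGAR give the offsets of the aligned
    part within the full read; on the reverse strand the CIGAR is stated in
    mapping orientation, so the leading clip is the distance from the read's
    *3'* end and the clip roles must be swapped.
    """
    left_clip = 0
    i = 0
    while i < len(cigar) and cigar[i][0] in _CLIP_OPS:
        left_clip += cigar[i][1]
        i += 1
    right_clip = 0
    j = len(cigar) - 1
    while j >= 0 and cigar[j][0] in _CLIP_OPS:
        right_clip += cigar[j][1]
        j -= 1
    aligned = sum(l for op, l in cigar if op in _QUERY_CONSUMING and op not in _CLIP_OPS)
    if is_reverse:
        left_clip, right_clip = right_clip, left_clip
    return left_clip, left_clip + aligned


def segment_from_record(rec: pysam.AlignedSegment) -> AlignmentSegment:
    """Convert one pysam record into an :class:`AlignmentSegment`."""
    cigar = tuple((_CIGAR_OPS[op], length) for op, length in rec.cigartuples)
    read_start, read_end = _read_coordinates(cigar, rec.is_reverse)
    return AlignmentSegment(
        read_name=rec.query_name,
        chrom=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        read_start=read_start,
        read_end=read_end,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
        cigar=cigar,
        is_supplementary=rec.is_supplementary,
    )


def read_alignment_file(
    path, min_mapq: int = DEFAULT_MIN_MAPQ
) -> Iterator[AlignmentSegment]:
    """Stream alignment segments from a SAM/BAM file.

    Yields one segment per primary or supplementary record with mapping
    quality >= ``min_mapq``.  No index is required; the file is scanned
    sequentially.  Records without a CIGAR are skipped with a warning.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if not rec.cigartuples:
                logger.warning("record %s has no CIGAR; skipped", rec.query_name)
                continue
            yield segment_from_record(rec)


def group_segments_by_read(
    segments: Iterable[AlignmentSegment],
) -> Dict[str, List[AlignmentSegment]]:
    """Partition segments by read name, ordered along the read.

    Within each group, segments are sorted by position on the original
    read; ties are broken by reference start, then chromosome.
    """
    groups: Dict[str, List[AlignmentSegment]] = defaultdict(list)
    for seg in segments:
        groups[seg.read_name].append(seg)
    for segs in groups.values():
        segs.sort(key=lambda s: (s.read_start, s.ref_start, s.chrom))
    return dict(groups)
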