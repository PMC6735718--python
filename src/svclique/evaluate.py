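"""Benchmarking of call sets against simulated truth.

Calls are matched 1-to-1 to truth variants by reciprocal overlap, the
standard interval-similarity criterion for SV benchmarking: the overlap
length divided by the longer... more precisely the minimum over both
intervals of overlap/length, so both intervals must be mostly shared.
Precision/recall curves sweep the cluster-score cutoff, mirroring how a
caller's score threshold trades recall against precision.

Insertion-class events (interspersed duplications and novel insertions)
occupy a single reference point, so interval overlap is meaningless for
them; when matching class-aware, they are compared by insertion-point
distance (<= 100 bp) combined with the ratio of the inserted lengths,
and the two insertion classes are evaluated jointly as "insertions".
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from svclique.model import SVCall, TruthVariant

INSERTION_CLASSES = {"interspersed_duplication", "novel_insertion"}
INSERTION_POINT_DISTANCE = 100


def reciprocal_overlap(a: Tuple[str, int, int], b: Tuple[str, int, int]) -> float:
    """min(ov/len(a), ov/len(b)) under half-open semantics; 0 across
    chromosomes.  Zero-length intervals count as length 1 (point events)."""
    if a[0] != b[0]:
        return 0.0
    ov = min(a[2], b[2]) - max(a[1], b[1])
    if ov <= 0:
        return 0.0
    len_a = max(1, a[2] - a[1])
    len_b = max(1, b[2] - b[1])
    return min(ov / len_a, ov / len_b)


def _class_group(sv_class: str) -> str:
    return "insertion" if sv_class in INSERTION_CLASSES else sv_class


def _similarity(call: SVCall, t: TruthVariant, class_aware: bool) -> float:
    if class_aware:
        if _class_group(call.sv_class) != _class_group(t.sv_class):
            return 0.0
        if _class_group(call.sv_class) == "insertion":
            if call.chrom != t.chrom:
                return 0.0
            if abs(call.begin - t.begin) > INSERTION_POINT_DISTANCE:
                return 0.0
            len_c = max(1, call.end - call.begin)
            len_t = max(1, t.end - t.begin)
            return min(len_c, len_t) / max(len_c, len_t)
    return reciprocal_overlap(
        (call.chrom, call.begin, call.end), (t.chrom, t.begin, t.end)
    )


def match_calls_to_truth(
    calls: Sequence[SVCall],
    truth: Sequence[TruthVariant],
    min_fraction: float = 0.5,
    class_aware: bool = True,
) -> Tuple[List[Tuple[SVCall, TruthVariant]], List[SVCall], List[TruthVariant]]:
    """Greedy 1-to-1 matching by decreasing similarity.

    Returns (true-positive pairs, false-positive calls, false-negative
    truth variants).  A pair matches iff its similarity >= min_fraction
    and, when class_aware, the classes agree with interspersed
    duplications and novel insertions pooled as insertions.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    scored = []
    for ci, call in enumerate(calls):
        for ti, t in enumerate(truth):
            sim = _similarity(call, t, class_aware)
            if sim >= min_fraction:
                scored.append((-sim, ci, ti))
    scored.sort()
    used_c: Set[int] = set()
    used_t: Set[int] = set()
    tp = []
    for _, ci, ti in scored:
        if ci in used_c or ti in used_t:
            continue
        tp.append((calls[ci], truth[ti]))
        used_c.add(ci)
        used_t.add(ti)
    fp = [c for i, c in enumerate(calls) if i not in used_c]
    fn = [t for i, t in enumerate(truth) if i not in used_t]
    return tp, fp, fn


def precision_recall_curve(
    calls: Sequence[SVCall],
    truth: Sequence[TruthVariant],
    min_fraction: float = 0.5,
    cutoffs: Optional[Iterable[float]] = None,
    class_aware: bool = True,
) -> pd.DataFrame:
    """One row per score cutoff: (cutoff, n_calls, tp, fp, fn, precision,
    recall).  Precision is NaN when no call survives a cutoff."""
    if cutoffs is None:
        cutoffs = range(0, 101, 10)
    rows = []
    for cutoff in cutoffs:
        surviving = [c for c in calls if c.score >= cutoff]
        tp, fp, fn = match_calls_to_truth(surviving, truth, min_fraction, class_aware)
        n_tp = len(tp)
        precision = n_tp / len(surviving) if surviving else float("nan")
        recall = n_tp / len(truth) if truth else 0.0
        rows.append(
            {
                "cutoff": cutoff,
                "n_calls": len(surviving),
                "tp": n_tp,
                "fp": len(fp),
                "fn": len(fn),
                "precision": precision,
                "recall": recall,
            }
        )
    return pd.DataFrame(rows)
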