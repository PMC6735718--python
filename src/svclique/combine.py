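"""COMBINE stage: classify signature clusters into five SV classes.

DEL, INV and TAN clusters map directly to deletion, inversion and tandem
duplication calls.  DUP clusters become interspersed duplications with
the origin their members reported.  INS clusters are matched against
nearby BRK clusters: a match identifies the origin of the inserted
sequence via the breakend's mate locus, turning the insertion into an
interspersed duplication; unmatched INS clusters are novel insertions.
Interspersed duplications whose origin overlaps a deletion call are
flagged as potential cut&paste events (the segment appears to have moved
rather than been copied).  BRK clusters without an INS partner are
dropped: standalone translocation calling is out of scope.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

from svclique.model import SignatureCluster, SVCall

DEFAULT_MATCH_DISTANCE = 100


def match_ins_to_brk(
    ins_clusters: List[SignatureCluster],
    brk_clusters: List[SignatureCluster],
    match_distance: int = DEFAULT_MATCH_DISTANCE,
) -> Tuple[List[Tuple[SignatureCluster, SignatureCluster]], List[SignatureCluster]]:
    """Greedy 1-to-1 pairing of insertion clusters with nearby breakends.

    Each INS cluster is paired with the closest same-chromosome BRK
    cluster whose breakpoint lies within ``match_distance`` of the
    insertion point; ties prefer the lower-coordinate INS.  Every BRK
    is used at most once.  Returns (pairs, unmatched INS clusters).
    """
    candidates = []
    for ins in ins_clusters:
        for brk in brk_clusters:
            if brk.chrom != ins.chrom:
                continue
            dist = abs(brk.begin - ins.begin)
            if dist <= match_distance:
                candidates.append((dist, ins.begin, id(ins), ins, brk))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    pairs = []
    used_ins, used_brk = set(), set()
    for dist, _, _, ins, brk in candidates:
        if id(ins) in used_ins or id(brk) in used_brk:
            continue
        pairs.append((ins, brk))
        used_ins.add(id(ins))
        used_brk.add(id(brk))
    unmatched = [ins for ins in ins_clusters if id(ins) not in used_ins]
    return pairs, unmatched


def _overlaps(a: Tuple[str, int, int], b: Tuple[str, int, int]) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def annotate_cutpaste(
    dup_calls: List[SVCall], deletion_calls: List[SVCall]
) -> List[SVCall]:
    """Flag interspersed duplications whose origin overlaps a deletion.

    Overlap is half-open and requires at least one shared base; abutting
    intervals do not count.  Only the ``cutpaste`` field changes.
    """
    for call in dup_calls:
        call.cutpaste = any(
            _overlaps(call.origin, (d.chrom, d.begin, d.end))
            for d in deletion_calls
        )
    return dup_calls


_DIRECT = {"DEL": "deletion", "INV": "inversion", "TAN": "tandem_duplication"}


def _call_from_cluster(
    cluster: SignatureCluster,
    sv_class: str,
    origin: Optional[Tuple[str, int, int]] = None,
) -> SVCall:
    return SVCall(
        sv_class=sv_class,
        chrom=cluster.chrom,
        begin=cluster.begin,
        end=cluster.end,
        score=cluster.score.total,
        support=len(cluster.members),
        read_names=cluster.read_names,
        origin=origin,
    )


def combine_clusters(
    clusters: List[SignatureCluster],
    match_distance: int = DEFAULT_MATCH_DISTANCE,
) -> List[SVCall]:
    """Turn signature clusters into classified SV calls.

    Every DEL/INV/TAN/DUP/INS cluster yields exactly one call; BRK
    clusters only ever contribute origins to insertion calls.
    """
    calls: List[SVCall] = []
    ins_clusters, brk_clusters = [], []
    for cluster in clusters:
        if cluster.sig_type in _DIRECT:
            calls.append(_call_from_cluster(cluster, _DIRECT[cluster.sig_type]))
        elif cluster.sig_type == "DUP":
            calls.append(
                _call_from_cluster(
                    cluster, "interspersed_duplication", cluster.origin_consensus
                )
            )
        elif cluster.sig_type == "INS":
            ins_clusters.append(cluster)
        elif cluster.sig_type == "BRK":
            brk_clusters.append(cluster)

    pairs, unmatched = match_ins_to_brk(ins_clusters, brk_clusters, match_distance)
    for ins, brk in pairs:
        mate_chrom, mate_pos = brk.mate_consensus
        ins_len = ins.end - ins.begin
        calls.append(
            _call_from_cluster(
                ins,
                "interspersed_duplication",
                (mate_chrom, mate_pos, mate_pos + ins_len),
            )
        )
    for ins in unmatched:
        calls.append(_call_from_cluster(ins, "novel_insertion"))

    dup_calls = [c for c in calls if c.sv_class == "interspersed_duplication"]
    deletion_calls = [c for c in calls if c.sv_class == "deletion"]
    annotate_cutpaste(dup_calls, deletion_calls)

    calls.sort(key=lambda c: (c.chrom, c.begin, c.end, c.sv_class))
    return calls
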