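"""CLUSTER stage: merge signatures across reads and score the clusters.

Signatures of the same type and chromosome are turned into an undirected
graph with an edge wherever the *span-position distance* (SPD) between
two signatures is below a threshold T.  For signatures S1, S2 with
intervals [B, E):

    SPD = SD + PD / N
    SD  = |span1 - span2| / max(span1, span2)          (in [0, 1))
    PD  = min(|B1 - B2|, |E1 - E2|, |mid1 - mid2|)      (bp)

N (default 900 bp) sets the exchange rate between positional offset and
span difference: signatures 900 bp apart with equal spans are as distant
as co-located signatures with maximally different spans.  Clusters are
the maximal cliques of the graph; each is scored 0-100 from four
features: member count (capped per evidence class), an evidence-class
bonus, and the positional and span consistency of its members.
"""

from __future__ import annotations

import statistics
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from svclique.model import (
    ClusterParams,
    ScoreComponents,
    Signature,
    SignatureCluster,
)


def span_position_distance(
    s1: Signature, s2: Signature, normalization_n: float = 900.0
) -> float:
    """Span-position distance between two signatures of one type/chromosome.

    Symmetric, zero iff the intervals are identical.  For two zero-span
    signatures (breakends) the span term is defined as 0, so breakend
    clustering degenerates to purely positional clustering.
    """
    span1 = s1.end - s1.begin
    span2 = s2.end - s2.begin
    max_span = max(span1, span2)
    sd = abs(span1 - span2) / max_span if max_span > 0 else 0.0
    pd = min(
        abs(s1.begin - s2.begin),
        abs(s1.end - s2.end),
        abs(s1.midpoint - s2.midpoint),
    )
    return sd + pd / normalization_n


def partition_signatures(
    signatures: Iterable[Signature],
) -> Dict[Tuple[str, str], List[Signature]]:
    """Bucket signatures by (type, chromosome), sorted by begin.

    Pairs in different buckets can never be joined by an edge, and within
    a bucket pairs with PD >= N*T are provably non-adjacent, so graph
    construction never has to compare across buckets.
    """
    buckets: Dict[Tuple[str, str], List[Signature]] = {}
    for sig in signatures:
        buckets.setdefault((sig.sig_type, sig.chrom), []).append(sig)
    for sigs in buckets.values():
        sigs.sort(key=lambda s: (s.begin, s.end, s.read_name))
    return buckets


def build_graph(
    bucket: Sequence[Signature], params: ClusterParams, prune: bool = True
) -> "nx.Graph":
    """Signature graph of one bucket: edge iff SPD < T (strict).

    With ``prune`` enabled, pairs whose positional difference alone already
    forces SPD >= T (PD >= N*T) are rejected without evaluating the span
    term; the resulting graph is identical to the unpruned one.  Breakend
    edges additionally require the mate loci to be within N*T bp.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(bucket)))
    n, t = params.normalization_n, params.edge_threshold_t
    pd_bound = n * t
    for i in range(len(bucket)):
        si = bucket[i]
        for j in range(i + 1, len(bucket)):
            sj = bucket[j]
            if prune and min(
                abs(si.begin - sj.begin),
                abs(si.end - sj.end),
                abs(si.midpoint - sj.midpoint),
            ) >= pd_bound:
                continue
            if si.sig_type == "BRK":
                mi, mj = si.mate, sj.mate
                if mi[0] != mj[0] or abs(mi[1] - mj[1]) >= pd_bound:
                    continue
            if span_position_distance(si, sj, n) < t:
                g.add_edge(i, j)
    return g


def enumerate_maximal_cliques(graph: "nx.Graph") -> List[Set[int]]:
    """All maximal cliques (Bron-Kerbosch with pivoting).

    Isolated vertices come back as singleton cliques.  Output is
    deterministic: cliques sorted by their sorted vertex tuple.
    """
    cliques = [set(c) for c in nx.find_cliques(graph)]
    cliques.sort(key=lambda c: tuple(sorted(c)))
    return cliques


def score_cluster(
    members: Sequence[Signature], params: Optional[ClusterParams] = None
) -> ScoreComponents:
    """Score a cluster from four features.

    n  = min(cap, #intra) + min(cap, #inter), cap 20 per evidence class
    b  = 10 if any intra, plus 20 if any inter
    sp = 10 * (1 - min(1, s_pos / mean_span))
    ss = 20 * (1 - min(1, s_span / mean_span))

    s_pos and s_span are population standard deviations of the member
    midpoints and spans (population so singletons get 0 rather than a
    division by zero).  For clusters of zero mean span (all breakends)
    the consistency terms award full points when the corresponding
    standard deviation is 0 and nothing otherwise.  The total is clamped
    into (0, 100].
    """
    if not members:
        raise ValueError("cannot score an empty cluster")
    params = params or ClusterParams()
    cap = params.max_counted_per_class
    n_intra = sum(1 for m in members if m.evidence_class == "intra")
    n_inter = len(members) - n_intra
    n = min(cap, n_intra) + min(cap, n_inter)
    b = (10 if n_intra else 0) + (20 if n_inter else 0)

    mids = [m.midpoint for m in members]
    spans = [float(m.span) for m in members]
    s_pos = statistics.pstdev(mids) if len(members) > 1 else 0.0
    s_span = statistics.pstdev(spans) if len(members) > 1 else 0.0
    mean_span = sum(spans) / len(spans)
    if mean_span > 0:
        sp = 10.0 * (1.0 - min(1.0, s_pos / mean_span))
        ss = 20.0 * (1.0 - min(1.0, s_span / mean_span))
    else:
        sp = 10.0 if s_pos == 0 else 0.0
        ss = 20.0 if s_span == 0 else 0.0
    total = min(100.0, max(1.0, n + b + sp + ss))
    return ScoreComponents(
        n=n, b=b, sp=sp, ss=ss,
        s_pos=s_pos, s_span=s_span, mean_span=mean_span, total=total,
    )


def resolve_overlapping_cliques(
    cliques: List[Set[int]], bucket: Sequence[Signature],
    params: Optional[ClusterParams] = None,
) -> List[Set[int]]:
    """Assign each signature to exactly one clique.

    Maximal cliques can share vertices; each signature should support one
    variant only.  Cliques are consumed greedily in decreasing order of
    (size, preliminary score, leftmost position); vertices already taken
    are removed from later cliques and emptied cliques are dropped.
    """
    def rank(c: Set[int]):
        score = score_cluster([bucket[i] for i in c], params).total
        leftmost = min(bucket[i].begin for i in c)
        return (-len(c), -score, leftmost, tuple(sorted(c)))

    taken: Set[int] = set()
    out: List[Set[int]] = []
    for c in sorted(cliques, key=rank):
        remaining = c - taken
        if remaining:
            out.append(remaining)
            taken |= remaining
    return out


def _median_int(values: Sequence[float]) -> int:
    return int(round(statistics.median(values)))


def _make_cluster(
    members: List[Signature], params: ClusterParams
) -> SignatureCluster:
    begin = _median_int([m.begin for m in members])
    end = _median_int([m.end for m in members])
    if end <= begin:
        end = begin + (1 if members[0].sig_type != "BRK" else 0)
    origin = None
    if members[0].sig_type == "DUP":
        origin = (
            members[0].origin[0],
            _median_int([m.origin[1] for m in members]),
            _median_int([m.origin[2] for m in members]),
        )
    mate = None
    if members[0].sig_type == "BRK":
        mate = (
            members[0].mate[0],
            _median_int([m.mate[1] for m in members]),
        )
    return SignatureCluster(
        sig_type=members[0].sig_type,
        members=members,
        chrom=members[0].chrom,
        begin=begin,
        end=end,
        score=score_cluster(members, params),
        origin_consensus=origin,
        mate_consensus=mate,
    )


def cluster_signatures(
    signatures: Iterable[Signature], params: Optional[ClusterParams] = None
) -> List[SignatureCluster]:
    """Full clustering: partition, graph, maximal cliques, overlap
    resolution, consensus interval (median begin/end) and scoring."""
    params = params or ClusterParams()
    buckets = partition_signatures(signatures)
    clusters: List[SignatureCluster] = []
    for key in sorted(buckets):
        bucket = buckets[key]
        graph = build_graph(bucket, params)
        cliques = enumerate_maximal_cliques(graph)
        for clique in resolve_overlapping_cliques(cliques, bucket, params):
            members = [bucket[i] for i in sorted(clique)]
            clusters.append(_make_cluster(members, params))
    clusters.sort(key=lambda c: (c.chrom, c.begin, c.end, c.sig_type))
    return clusters
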