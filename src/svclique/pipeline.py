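"""End-to-end orchestration: alignments in, classified SV calls out."""

from __future__ import annotations

import logging
from collections import Counter
from typing import List, Union

from svclique import alignment_io, combine, signatures
from svclique.clustering import ClusterParams, cluster_signatures
from svclique.model import SVCall

logger = logging.getLogger(__name__)


def call_variants(
    alignment_path,
    min_mapq: int = alignment_io.DEFAULT_MIN_MAPQ,
    min_sv_size: int = signatures.DEFAULT_MIN_SV_SIZE,
    params: Union[ClusterParams, None] = None,
    match_distance: int = combine.DEFAULT_MATCH_DISTANCE,
) -> List[SVCall]:
    """Run collect -> cluster -> combine on a SAM/BAM file."""
    params = params or ClusterParams()
    segments = list(alignment_io.read_alignment_file(alignment_path, min_mapq))
    grouped = alignment_io.group_segments_by_read(segments)
    logger.info("collected %d segments from %d reads", len(segments), len(grouped))

    sigs = signatures.collect_signatures(grouped, min_sv_size=min_sv_size)
    logger.info(
        "signatures per type: %s", dict(Counter(s.sig_type for s in sigs))
    )

    clusters = cluster_signatures(sigs, params)
    logger.info("built %d signature clusters", len(clusters))

    calls = combine.combine_clusters(clusters, match_distance)
    logger.info(
        "calls per class: %s", dict(Counter(c.sv_class for c in calls))
    )
    return calls
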