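"""Core domain types shared by all pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; the VCF
writer is the only place that converts to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Signature types emitted by the collection stage.
SIG_TYPES = ("DEL", "INS", "DUP", "INV", "TAN", "BRK")

#: SV classes emitted by the combination stage.
SV_CLASSES = (
    "deletion",
    "inversion",
    "tandem_duplication",
    "interspersed_duplication",
    "novel_insertion",
)


@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned piece of a read.

    ``read_start``/``read_end`` are expressed on the original (forward
    orientation, unclipped) read, so that segments of one read can be
    ordered along the molecule regardless of mapping strand.
    """

    read_name: str
    chrom: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str  # '+' or '-'
    mapq: int
    cigar: tuple  # tuple of (op, length); op is a SAM CIGAR character
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if not self.ref_start < self.ref_end:
            raise ValueError(
                f"ref_start must be < ref_end: {self.ref_start} >= {self.ref_end}"
            )
        if not self.read_start < self.read_end:
            raise ValueError(
                f"read_start must be < read_end: {self.read_start} >= {self.read_end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-': {self.strand!r}")


@dataclass(frozen=True)
class Signature:
    """Evidence from a single read for a candidate SV.

    A signature is the quadruple (type, chromosome, begin, end) plus its
    evidence class and provenance.  For insertions ``end - begin`` equals
    the inserted length, so span comparisons during clustering compare
    inserted lengths.  DUP signatures carry the genomic origin of the
    duplicated segment; BRK signatures carry the mate locus of the
    junction.
    """

    sig_type: str
    chrom: str
    begin: int
    end: int
    evidence_class: str  # 'intra' or 'inter'
    read_name: str
    origin: Optional[tuple] = None  # (chrom, begin, end) for DUP
    mate: Optional[tuple] = None  # (chrom, pos) for BRK

    def __post_init__(self) -> None:
        if self.sig_type not in SIG_TYPES:
            raise ValueError(f"unknown signature type {self.sig_type!r}")
        if self.begin > self.end:
            raise ValueError(f"begin > end: {self.begin} > {self.end}")
        if self.evidence_class not in ("intra", "inter"):
            raise ValueError(f"bad evidence class {self.evidence_class!r}")
        if self.evidence_class == "intra" and self.sig_type not in ("DEL", "INS"):
            raise ValueError("intra-alignment signatures can only be DEL or INS")
        if self.sig_type == "DUP" and not self.origin:
            raise ValueError("DUP signatures require an origin locus")
        if self.sig_type == "BRK" and not self.mate:
            raise ValueError("BRK signatures require a mate locus")

    @property
    def span(self) -> int:
        return self.end - self.begin

    @property
    def midpoint(self) -> float:
        return (self.begin + self.end) / 2.0


@dataclass(frozen=True)
class ClusterParams:
    """Tunables of the clustering stage.

    ``normalization_n`` (N) balances span difference against positional
    difference in the span-position distance: a positional offset of N bp
    weighs as much as a maximal span difference.  An edge is drawn between
    two signatures when their distance is strictly below
    ``edge_threshold_t`` (T).
    """

    normalization_n: float = 900.0
    edge_threshold_t: float = 0.7
    max_counted_per_class: int = 20

    def __post_init__(self) -> None:
        if self.normalization_n <= 0:
            raise ValueError("normalization_n must be positive")
        if self.edge_threshold_t <= 0:
            raise ValueError("edge_threshold_t must be positive")


@dataclass(frozen=True)
class ScoreComponents:
    """The four cluster-score components and their total.

    n  — signature count, at most 20 per evidence class, in (0, 40]
    b  — evidence-class bonus: 10 for >=1 intra, 20 for >=1 inter
    sp — positional consistency, 10 * (1 - min(1, s_pos / mean_span))
    ss — span consistency,       20 * (1 - min(1, s_span / mean_span))
    """

    n: int
    b: int
    sp: float
    ss: float
    s_pos: float
    s_span: float
    mean_span: float
    total: float


@dataclass
class SignatureCluster:
    """A maximal clique of mutually compatible signatures."""

    sig_type: str
    members: list  # of Signature
    chrom: str
    begin: int
    end: int
    score: ScoreComponents
    origin_consensus: Optional[tuple] = None  # (chrom, begin, end)
    mate_consensus: Optional[tuple] = None  # (chrom, pos) for BRK clusters

    @property
    def read_names(self) -> list:
        return sorted({m.read_name for m in self.members})


@dataclass
class SVCall:
    """A classified structural variant."""

    sv_class: str
    chrom: str
    begin: int
    end: int
    score: float
    support: int
    read_names: list = field(default_factory=list)
    origin: Optional[tuple] = None  # interspersed_duplication only
    cutpaste: bool = False

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown SV class {self.sv_class!r}")
        if (self.origin is not None) != (self.sv_class == "interspersed_duplication"):
            raise ValueError("origin present iff class is interspersed_duplication")
        if self.cutpaste and self.origin is None:
            raise ValueError("cutpaste requires an origin")


@dataclass(frozen=True)
class TruthVariant:
    """A simulated ground-truth SV used by the evaluation harness."""

    sv_class: str
    chrom: str
    begin: int
    end: int
    length: int
    zygosity: str = "hom"  # 'hom' or 'het'
    origin: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown SV class {self.sv_class!r}")
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")
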