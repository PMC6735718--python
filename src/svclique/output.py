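"""Serialization of SV calls: five BED files and one VCF.

BED output keeps the package's 0-based half-open convention; the VCF
writer converts to 1-based positions and encodes the five classes as
symbolic ALT alleles (<DEL>, <INV>, <DUP:TANDEM>, <DUP:INT>, <INS>).
Interspersed duplications carry their genomic origin in CHR2/POS2/END2
and the cut&paste annotation as a flag.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Union

from pyfaidx import Fasta

from svclique.model import SVCall

BED_FILENAMES = {
    "deletion": "deletions.bed",
    "inversion": "inversions.bed",
    "tandem_duplication": "tandem_duplications.bed",
    "interspersed_duplication": "interspersed_duplications.bed",
    "novel_insertion": "novel_insertions.bed",
}


def _bed_name(call: SVCall) -> str:
    if call.sv_class == "interspersed_duplication":
        oc, ob, oe = call.origin
        return f"origin={oc}:{ob}-{oe};cutpaste={'true' if call.cutpaste else 'false'}"
    return call.sv_class


def write_bed_files(
    calls: List[SVCall], out_dir: Union[str, Path], min_score: float = 0.0
) -> List[Path]:
    """Write one BED file per SV class into ``out_dir``.

    Columns: chrom, start, end, name, score (1 decimal).  Only calls with
    score >= ``min_score`` are written; records are sorted by chrom and
    start.  Returns the five paths (files are created even when empty).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_class: Dict[str, List[SVCall]] = {c: [] for c in BED_FILENAMES}
    for call in calls:
        if call.score >= min_score:
            by_class[call.sv_class].append(call)
    paths = []
    for sv_class, filename in BED_FILENAMES.items():
        path = out_dir / filename
        records = sorted(by_class[sv_class], key=lambda c: (c.chrom, c.begin, c.end))
        with open(path, "w") as fh:
            for call in records:
                fh.write(
                    f"{call.chrom}\t{call.begin}\t{call.end}\t"
                    f"{_bed_name(call)}\t{call.score:.1f}\n"
                )
        paths.append(path)
    return paths


_ALT = {
    "deletion": "<DEL>",
    "inversion": "<INV>",
    "tandem_duplication": "<DUP:TANDEM>",
    "interspersed_duplication": "<DUP:INT>",
    "novel_insertion": "<INS>",
}
_SVTYPE = {
    "deletion": "DEL",
    "inversion": "INV",
    "tandem_duplication": "DUP:TANDEM",
    "interspersed_duplication": "DUP:INT",
    "novel_insertion": "INS",
}

_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of supporting signatures">',
    '##INFO=<ID=CHR2,Number=1,Type=String,Description="Chromosome of the duplication origin">',
    '##INFO=<ID=POS2,Number=1,Type=Integer,Description="Start of the duplication origin (1-based)">',
    '##INFO=<ID=END2,Number=1,Type=Integer,Description="End of the duplication origin">',
    '##INFO=<ID=CUTPASTE,Number=0,Type=Flag,Description="Origin overlaps a deletion: potential cut&paste insertion">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=INV,Description="Inversion">',
    '##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">',
    '##ALT=<ID=DUP:INT,Description="Interspersed duplication">',
    '##ALT=<ID=INS,Description="Novel element insertion">',
]


def _contig_lengths(reference) -> Dict[str, int]:
    if isinstance(reference, dict):
        return dict(reference)
    fasta = Fasta(str(reference))
    return {name: len(fasta[name]) for name in fasta.keys()}


def _svlen(call: SVCall) -> int:
    length = call.end - call.begin
    return -length if call.sv_class == "deletion" else length


def write_vcf(
    calls: List[SVCall],
    reference: Union[str, Path, Dict[str, int]],
    out_path: Union[str, Path],
) -> Path:
    """Write all calls as a VCF 4.2 file with symbolic ALT alleles.

    ``reference`` is either a FASTA path or a {contig: length} mapping;
    contigs are needed for the header, and a call on a contig missing
    from it raises ValueError.  QUAL carries the cluster score.
    """
    contigs = _contig_lengths(reference)
    for call in calls:
        if call.chrom not in contigs:
            raise ValueError(f"call on contig {call.chrom!r} absent from reference")
    out_path = Path(out_path)
    records = sorted(calls, key=lambda c: (c.chrom, c.begin, c.end, c.sv_class))
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=svclique\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, call in enumerate(records, start=1):
            # padding-base convention: POS is the base before the event,
            # which in 1-based coordinates equals the 0-based begin
            pos = max(1, call.begin)
            inserted = call.sv_class in ("novel_insertion",
                                         "interspersed_duplication")
            info = [
                f"SVTYPE={_SVTYPE[call.sv_class]}",
                f"END={pos if inserted else call.end}",
                f"SVLEN={_svlen(call)}",
                f"SUPPORT={call.support}",
            ]
            if call.sv_class == "interspersed_duplication":
                oc, ob, oe = call.origin
                info.append(f"CHR2={oc}")
                info.append(f"POS2={ob + 1}")
                info.append(f"END2={oe}")
                if call.cutpaste:
                    info.append("CUTPASTE")
            fh.write(
                f"{call.chrom}\t{pos}\tsvclique.{_SVTYPE[call.sv_class]}.{i}"
                f"\tN\t{_ALT[call.sv_class]}\t{call.score:.1f}\tPASS\t"
                + ";".join(info) + "\n"
            )
    return out_path
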