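import pytest

from svclique import simulate
from svclique.model import AlignmentSegment, Signature


def make_segment(**kw):
    """AlignmentSegment with reasonable defaults for rule tests."""
    defaults = dict(
        read_name="r1", chrom="chr1", ref_start=0, ref_end=100,
        read_start=0, read_end=100, strand="+", mapq=60,
        cigar=(("M", 100),), is_supplementary=False,
    )
    defaults.update(kw)
    return AlignmentSegment(**defaults)


def make_sig(sig_type="DEL", chrom="chr1", begin=1000, end=1200,
             evidence_class="intra", read_name="r1", **kw):
    return Signature(sig_type, chrom, begin, end, evidence_class, read_name, **kw)


@pytest.fixture(scope="session")
def ideal_scenario():
    """500 kb genome, 60 implanted SVs, 6x idealized coverage (shared
    across tests because synthesis is the slow part)."""
    reference = simulate.simulate_reference(1, 500_000, seed=11)
    sim = simulate.implant_variants(
        reference,
        counts={
            "deletion": 20,
            "inversion": 10,
            "tandem_duplication": 10,
            "interspersed_duplication": 15,
            "novel_insertion": 5,
        },
        size_range=(50, 500),
        seed=11,
    )
    return sim


@pytest.fixture(scope="session")
def ideal_sam(ideal_scenario, tmp_path_factory):
    path = tmp_path_factory.mktemp("sim") / "ideal.sam"
    simulate.synthesize_alignments(
        ideal_scenario, coverage=6.0, out_sam=path, mode="idealized", seed=12
    )
    return path
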