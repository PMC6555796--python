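import numpy as np
import pytest

from refgraft.alignment_io import CigarOp, ContigAlignment
from refgraft.simulate import (
    SimConfig,
    plant_deletions,
    plant_variants,
    sim_contig_alignments,
    sim_reference,
)


def make_alignment(
    cigar,
    ref_start=10_000,
    contig_id="ctg1",
    ref_name="chr1",
    strand="+",
    mapq=60,
    seq=None,
    contig_length=None,
    is_supplementary=False,
):
    """Build a consistent ContigAlignment from a CIGAR op list."""
    ops = tuple(CigarOp(c, n) for c, n in cigar)
    lead = 0
    for op in ops:
        if op.code in "SH":
            lead += op.length
        else:
            break
    trail = 0
    for op in reversed(ops):
        if op.code in "SH":
            trail += op.length
        else:
            break
    q_span = sum(op.length for op in ops if op.code in "MI=X")
    r_span = sum(op.length for op in ops if op.code in "MDN=X")
    total = lead + q_span + trail
    if strand == "+":
        q0, q1 = lead, lead + q_span
    else:
        q0, q1 = trail, trail + q_span
    return ContigAlignment(
        contig_id=contig_id,
        ref_name=ref_name,
        ref_start=ref_start,
        ref_end=ref_start + r_span,
        strand=strand,
        mapq=mapq,
        cigar=ops,
        query_start=q0,
        query_end=q1,
        contig_length=contig_length or total,
        seq=seq,
        is_supplementary=is_supplementary,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded genome with planted insertions and deletions."""
    config = SimConfig(
        seed=11,
        chrom_lengths={"chr1": 600_000},
        n_insertions=8,
        n_deletions=4,
        n_individuals=20,
    )
    reference = sim_reference(config)
    truth, genotypes = plant_variants(reference, config)
    deletions = plant_deletions(reference, config)
    alignments, contigs = sim_contig_alignments(truth, reference, config, deletions)
    return {
        "config": config,
        "reference": reference,
        "truth": truth,
        "genotypes": genotypes,
        "deletions": deletions,
        "alignments": alignments,
        "contigs": contigs,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(123)
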