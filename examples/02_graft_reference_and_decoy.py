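"""Graft verified insertions into a reference and build the decoy contig.

Shows the three integration cases (split distance 0 / positive / negative),
the per-chromosome length identity the liftover chain guarantees, and the
decoy's insertion + 20-N-spacer layout.
"""

from refgraft import ref_build, sv_detect
from refgraft.simulate import (
    SimConfig, plant_variants, sim_contig_alignments, sim_reference,
)

config = SimConfig(
    seed=7, chrom_lengths={"chr1": 500_000}, n_insertions=8, n_individuals=4
)
reference = sim_reference(config)
truth, _ = plant_variants(reference, config)
alignments, contigs = sim_contig_alignments(truth, reference, config)
calls = sv_detect.assign_ids(
    sv_detect.detect_ins_intra(alignments, contigs=contigs)
    + sv_detect.detect_ins_inter(alignments, contigs=contigs)
)

plan = ref_build.build_integration_plan(calls, reference)
augmented, chain = ref_build.apply_integration(reference, plan)

src, dst = len(reference["chr1"]), len(augmented["chr1"])
delta = sum(len(e.insert_seq) - e.delete_len for e in plan)
print(f"chr1: {src:,} bp -> {dst:,} bp (increase {delta:,} bp from {len(plan)} edits)")
print(f"length identity holds: {dst == src + delta}")

pos = 123_456
lifted = chain.lift("chr1", pos)
print(f"source position {pos} lifts to {lifted} and back to "
      f"{chain.lift_back('chr1', lifted)}")

decoy = ref_build.build_decoy(calls)
total_ins = sum(c.length for c in calls)
print(f"\ndecoy: {len(calls)} insertions + 20-N spacers -> {decoy.length:,} bp "
      f"(= {total_ins:,} + {20 * len(calls)})")
# The decoy gives reads from novel sequence a correct alignment target, so
# they stop mismapping onto similar regions of the primary assembly.
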