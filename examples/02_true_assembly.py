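"""Build the true assembly of a read set, exactly and by estimation.

The true assembly at minimum overlap w is what an ideal assembler would
output given the true origin of every read.  With simulated reads the
origins are known; with real reads they are estimated by posterior sampling
against a reference transcript set.
"""

from asmeval import ModelParams
from asmeval.simulate import SimConfig, simulate_reads, simulate_transcriptome
from asmeval.true_assembly import (
    contigs_to_assembly,
    estimate_true_assembly,
    true_contigs,
)

config = SimConfig(n_transcripts=10, N=3000, L=50, epsilon=0.002, seed=11)
transcripts, tau = simulate_transcriptome(config)
reads = simulate_reads(transcripts, tau, config)

for w in (0, 1, 10, 25):
    contigs = true_contigs(reads, transcripts, w=w)
    print(f"w={w:2d}: {len(contigs)} true contigs, "
          f"{sum(c.length for c in contigs)} bases")

# Higher w demands more read overlap to extend a contig, so the assembly
# fragments and duplicates overlap regions; w=0 is the best achievable.

estimated = estimate_true_assembly(
    reads, transcripts, ModelParams(L=50, epsilon=0.002), seed=1, w=0
)
exact = contigs_to_assembly(true_contigs(reads, transcripts, w=0))
same = sorted(c.seq for c in estimated) == sorted(c.seq for c in exact)
print(f"estimated assembly: {estimated.M} contigs; "
      f"identical to the origin-based truth: {same}")
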