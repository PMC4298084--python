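"""Score an assembly against the reads used to build it.

Simulates a small transcriptome, builds the best theoretically achievable
assembly (the true assembly at minimum overlap 0), and prints the
reference-free score breakdown for it and for a damaged variant.
"""

from asmeval import ModelParams, Scorer
from asmeval.score import estimate_prior_from_lengths
from asmeval.simulate import SimConfig, perturb_substitution, simulate_reads, simulate_transcriptome
from asmeval.true_assembly import contigs_to_assembly, true_contigs

config = SimConfig(n_transcripts=30, N=20_000, L=76, epsilon=0.005, seed=7)
transcripts, tau = simulate_transcriptome(config)
reads = simulate_reads(transcripts, tau, config)

truth = contigs_to_assembly(true_contigs(reads, transcripts, w=0))
damaged = perturb_substitution(truth, rate=1e-3, seed=1)

params = ModelParams(L=config.L, epsilon=config.epsilon)
prior = estimate_prior_from_lengths([len(t) for t in transcripts])
scorer = Scorer(reads, params, prior, exact_prior=False)

for name, asm in (("true assembly", truth), ("0.1% substitutions", damaged)):
    bd = scorer.score(asm)
    print(f"{name}: {asm.M} contigs")
    print(f"  log-likelihood (uncorrected) {bd.loglik_uncorrected:14.1f}")
    print(f"  coverage correction          {-bd.log_correction:14.1f}")
    print(f"  assembly prior               "
          f"{bd.log_contig_length_prior + bd.log_assembly_size_prior:14.1f}")
    print(f"  BIC penalty                  {-bd.bic_penalty:14.1f}")
    print(f"  total                        {bd.total:14.1f}")
    print(f"  normalized (vs null)         {bd.normalized:14.1f}")

# The total is the log joint probability of assembly and reads; higher is
# better.  The damaged assembly explains the reads worse (lower likelihood),
# so its total drops below the truth's.
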