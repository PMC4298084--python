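# Methods

## The evaluation problem

A de novo transcriptome assembly is a set of contigs reconstructed from
RNA-Seq reads without a genome. Simple reference-free statistics (N50,
contig counts) reward contiguity, not accuracy — concatenating all reads
into one contig maximizes N50. `asmeval` implements two complementary
answers: a reference-free probabilistic score of an assembly given the
reads that built it, and a set of reference-based measures for when a
trusted transcript set exists.

## The true assembly

Both halves of the package lean on the notion of the *true assembly at
minimum overlap length w*: the set of maximal transcript segments
`[start, end]` for which an ordered set of reads exists with every read
from that transcript, consecutive reads overlapping by at least `w` bases
(`w = 0` also admits exact adjacency), the first read starting the segment
and the last read ending it. It is the best assembly achievable by an
assembler that needs `w` bases of overlap to merge reads; `w = 0` is the
best achievable overall. `true_contigs` computes it with a left-to-right
sweep that tracks the rightmost covered position; a unit test checks the
sweep against exhaustive verification of the defining conditions on small
instances. With paired-end origins, contigs linked by a read pair are
chained into scaffolds (connected components of the contig/pair graph),
with uncovered gaps written as N runs sized by transcript coordinates.

For real reads, `estimate_true_assembly` reconstructs origins by aligning
reads to reference transcripts, fitting abundances by EM, and sampling one
alignment per read from its posterior (inverse-CDF over a deterministic
alignment order, so a seed makes the estimate reproducible). Reads sampled
to the noise component are dropped.

## The reference-free score

The score of assembly `A` given reads `D` is the log joint probability

    log P(A, D) ≈ log P(D | A, Λ_MLE)            (corrected likelihood)
                + log P(A | Λ_MLE)               (assembly prior)
                − ½ (M + 1) log N                (BIC penalty)

with natural logarithms; `M` contigs, `N` reads, and `Λ = {λ_i}` the
expected read coverage of each contig's parent transcript (reads starting
per valid position).

**Read model and EM.** Contigs are treated as transcripts. A read arises
from contig `i` with mixture weight `θ_i` — uniform start over the
`ℓ_i − L + 1` valid positions, uniform strand unless strand-specific, and
independent per-base substitution error `ε` (the three alternative bases
equiprobable) — or from a background noise component with weight `θ_0`
(default uniform base distribution). Candidate alignments are exhaustive
ungapped placements with at most `max_mismatches` (default 2) mismatches,
found by an exact-seed pigeonhole index (seed length 25; brute-force window
scan when the pigeonhole guarantee `⌊L/25⌋ ≥ max_mismatches + 1` does not
hold or contigs are shorter than a seed). Reads containing non-ACGT
characters are excluded from alignment (counted and logged) and fall to the
noise component. `Θ_MLE` is fitted by EM from a uniform initialization,
stopping when the relative log-likelihood change falls below `1e-4` (at
most 1000 iterations); the trace is recorded and non-decreasing. Coverages
follow from `λ_i = N θ_i / (ℓ_i + L + 1)` — the `+L+1` denominator (not
`−L+1`) accounts for the fact that no read can have started within `L`
bases of either side of a contig's reads, or the contig would have been
extended.

**Assembly prior.** Each contig is generated independently. Its parent
transcript has negative binomial length (parameters `(r, p)`; defaults give
mean 1500, a vertebrate transcriptome scale, and are re-estimable from any
transcript FASTA by method of moments with `r` clamped to `[0.1, 1000]`),
uniform sequence, and Poisson(λ) read starts per valid position. The
contigs of the resulting true assembly (model `w`, default 0) are pooled
into a conceptual bag; the frequency of lengths in the bag defines
`P(ℓ | λ)`, and the prior is `∏ P(ℓ_i | λ_i) · (1/4)^Σℓ_i`. The length
frequency is computed in closed form: with occupancy `q = 1 − e^{−λ}` per
start position, a contig of span `d = ℓ − L` is a maximal run whose
consecutive occupied positions are at most `G = L − w` apart. The expected
count of such runs factorizes into a run-interior connection probability
`u(d)` (a linear recurrence of order `G`, evaluated with an IIR filter), a
boundary factor `T(n)` (self-correlation of `(1−q)^{min(x,G)}`), and the
negative binomial transcript-length marginal (a convolution). The DP is
truncated at the NB 0.9999 quantile (rounded up when an assembly contains
longer contigs) and normalized over its support. Tests verify the DP
against a million-replicate Monte-Carlo simulation of the literal bag
process (total variation ≤ 0.01) and against exhaustive enumeration of
occupancy patterns for `u(d)`.

**Coverage correction.** The read model alone does not force reads to
cover the assembly, so the generative process rejects read sets that fail
to cover every contig with pairwise overlaps ≥ `w`. Conditioning on
acceptance divides the likelihood by `P(C = 1) = ∏_i P(contig i covered)`,
computed per contig with the same connection recurrence (start at the first
position, a read ending at the last, gaps ≤ `L − w`). We model read starts
as a Poisson process per position rather than conditioning on the realized
read count; the two agree closely at the data sizes involved, and the
Poisson device matches the prior's. A placement-simulation oracle checks
the per-contig probability to 0.01.

**Practical floors and clamps.**
* Contigs with `θ_i = 0` (or numerically tiny λ) use the floor
  `λ_min = 1/(ℓ_i + L + 1)` — one expected read — in the prior and
  correction terms. Without a floor, `−log P(C=1|λ)` grows without bound as
  `λ → 0`, which would let unexpressed contigs inflate the score.
* Contigs shorter than one read are impossible under the bag process
  (both `P(ℓ|λ)` and `P(C=1)` are zero). Inside the full score their length
  is clamped to `L` in those two terms only, so such contigs still pay the
  size prior and BIC, explain no reads, and strictly lower the score — the
  alternative (a ±∞ score) would make any assembly containing one sub-read
  fragment unrankable. The standalone functions keep the honest −∞.
* The null assembly (no contigs) has likelihood `Σ_r log P(r | noise)`,
  prior 0 and BIC `½ log N`; the *normalized* score is the total minus the
  null total, and is 0 for the null assembly by construction.

**Contig impact and trimming.** The impact of contig `i` compares the
hypothesis that it is a true contig against the hypothesis that its reads
are background noise: its posterior-apportioned read log-likelihood gain
over the noise model (including the reallocation of mixture weight
`θ_0 → θ_0 + θ_i` that dropping the contig implies), minus its coverage
correction, plus its length- and size-prior terms and its `½ log N` BIC
share. On instances where a contig shares no reads with others, the impact
equals the full-score change of removing the contig (verified to `1e-6`
against leave-one-out re-scoring). Trimming removes all contigs with
negative impact.

**Caching.** Scoring many assemblies of one read set reuses the encoded
read matrix and seed tables (`Scorer`). With `exact_prior=False`, length
prior values are interpolated in log λ on a geometric grid of 48 points per
decade with distributions cached per grid point; `contig_length_prior`
itself is always exact. The interpolation error is far below the score
differences the experiments measure, and the same path is used for a score
and its impacts, so the leave-one-out identity is unaffected.

## Reference-based measures

All measures run either from BLAT PSL alignments or from the internal
seed-and-extend aligner (exact 16-mer seeds clustered by diagonal, ungapped
X-drop extension, exact match/mismatch/indel accounting via a banded global
alignment of the clustered segments). Internal-aligner thresholds
(`min_matches=30`, `min_identity=0.7`) are documented knobs; on the
synthetic data used here it reliably recovers alignments of ≥ 95% identity
and ≥ 50 bases.

* **Contig level.** A reference sequence is correctly recovered when a
  single alignment makes ≥ 99% of its non-N bases identical to the matched
  assembly sequence *and vice versa*, with inserted plus deleted bases at
  most 1% of the shorter non-N length (the stricter of the two). Matching
  is one-to-one: the maximum-cardinality matching of the bipartite
  qualification graph (Hopcroft–Karp via networkx). Recall divides by the
  number of reference sequences, precision by the number of contigs,
  F1 is their harmonic mean (0 when both are 0). Scaffold evaluation uses
  the same routine; N runs are excluded by the non-N length convention.
* **Nucleotide level.** Alignments are selected greedily in order of their
  marginal contribution to newly-assigned correctly-recovered positions;
  a selected alignment claims every position it spans, and each position is
  assigned at most one alignment. Ties break toward the longer alignment,
  then lexicographic ids, for determinism. Precision swaps the roles of
  assembly and reference. Denominators count non-N positions. Note the
  greedy rule is a heuristic: orders exist that recover slightly more
  positions on adversarially overlapping alignments; tests check agreement
  with an independent replay of the rule and the upper bound, not
  optimality.
* **KC score.** `KC = WKR − ICR`. The weighted k-mer recall is
  `WKR = Σ_{r ∈ r(A)} p(r)` over the distinct k-mers of the assembly, with
  `p(r) = Σ_b n(r,b) τ(b) / Σ_b n(b) τ(b)` the abundance-weighted reference
  k-mer frequency; the inverse compression rate is `ICR = |A| / (N·L)`.
  `k` defaults to the read length. K-mers containing N are skipped; k-mers
  are counted strand-canonically unless the protocol is strand-specific.
  Abundances τ may be supplied or estimated from reads by EM (converting
  read fractions to molar fractions via effective lengths).
* **N50** follows the standard cumulative definition and is provided for
  comparison only.

## Synthetic data generators

`simulate_transcriptome` draws NB(r, p) lengths (clipped below at `L`),
uniform sequences and Dirichlet abundances; `simulate_reads` picks a
transcript with probability ∝ τ · (ℓ − L + 1) (so starts are uniform per
position, matching the coverage model), a uniform start, a random strand
unless strand-specific, and applies substitution errors at rate ε; origins
are encoded in read names as `{serial}_{tid}_{left}_{right}_{strand}`
(1-based inclusive, decodable even when the transcript id contains
underscores). The four perturbation generators follow the constructions
used in the validation experiments: per-base substitution; fusion of random
contig pairs with the longest shared suffix/prefix collapsed (head-to-tail,
no reverse complementing); fission at read-merge points with the overlapped
segment duplicated into both fragments (requires the `TrueContig` layout);
and indels with geometric(mean 3) lengths on positive support (success
probability 1/3), insertions random, deletions confined to one contig and
never removing it entirely.

What the generators do *not* emulate: position- and quality-dependent
error profiles, sequencing biases, paired-end fragment-length variation,
polymorphism, and homology between transcripts (isoforms exist only where
a scenario constructs them explicitly). Passing tests therefore demonstrate
the internal consistency of the model and its discriminative behaviour
under controlled conditions, not performance on any particular real
library.

## Validation experiments and problem sizes

All experiments derive every random stream from a single seed and run at
sizes chosen to keep the full suite comfortably runnable on one CPU:

* *Six-read construction*: the worked layout (overlap, exact adjacency,
  an uncovered gap) yields 2 contigs at `w=0` and 3 at `w=1`.
* *Two-isoform scenario*: a 1000-base isoform equal to the first half of a
  2000-base isoform, 90:10 abundance, 5000 reads of length 100 at 0.01%
  error; across 20 simulations the true two-isoform assembly must outscore
  the single-isoform assemblies in ≥ 18.
* *Random perturbation*: ground truth from 260 NB(2, mean 400) transcripts
  and 2×10⁵ reads of length 76 (ε = 0.005), ≥ 200 true contigs; 50
  replicates per class for substitution/fission/indel at rates
  {10⁻⁴, 10⁻³, 10⁻²}; mean normalized scores must fall monotonically and
  the strongest level must never beat the truth.
* *Guided perturbation*: true assemblies at
  `w ∈ {0, 1, 2, 5, 10, 25, 75}` from 40 transcripts and 3×10⁴ reads; the
  full score must peak at `w ≤ 2` and the uncorrected ML term at `w = 75`
  (shorter contigs mean fewer start positions, hence higher per-read
  position probability — exactly the pathology the prior corrects).
* *Oracle equivalence*: the length-prior DP vs a 10⁶-replicate bag
  simulation at λ ∈ {0.05, 0.5, 5} (TV ≤ 0.01; small NB(5, mean 60), L=25
  fixture so the Monte-Carlo sampling error stays well inside the bound),
  and the coverage DP vs a 10⁵-replicate placement simulation on contigs
  ≤ 400 bases (|Δ| ≤ 0.01).
* *EM recovery*: weights recovered within 0.02 absolute from 5000 reads
  over 8 non-homologous transcripts.
* *Trimming*: a 10-true + 5-junk assembly; trimming must remove ≥ 4 junk
  contigs, at most 1 true contig, and not lower nucleotide F1.
* *Score vs KC*: ≥ 10 assemblies of one read set spanning truth, perturbed,
  junk-padded and half-truth variants; Spearman correlation between the
  normalized reference-free score and the KC score ≥ 0.8.

`scripts/acceptance.py` recomputes all of the above from scratch from a
single `--seed`.

## Known limitations

Single-end likelihoods only (paired-end data participate in scaffold
construction and scaffold-level measures, not in the score); ungapped read
alignment (no indel alignments); a flat substitution error model without
quality scores; the score should only be applied to assemblies built from
the same reads, and not to genome-guided assemblies. Fusion perturbations
are implemented but excluded from the monotonicity claims: fusions of
low-coverage contigs are genuinely hard for a `w=0` ground-truth model to
reject, and the score's error rate for weak fusions is known to be high.
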