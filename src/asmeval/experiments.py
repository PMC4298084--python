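"""Validation experiments and Monte-Carlo oracles.

These drivers reproduce, at desk scale, the experiments that motivate the
scores: the two-isoform ranking scenario, random and guided perturbations
of a simulated ground truth, EM parameter recovery, impact-based trimming,
and the correlation between the reference-free score and the KC score.
The Monte-Carlo oracles simulate the literal generative processes behind
the assembly prior and the coverage correction, independently of the
closed-form implementations they are used to check.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .read_model import ModelParams
from .records import Assembly, SequenceRecord
from .ref_measures import kc_score, nucleotide_level_scores, align_assembly_to_reference
from .score import (
    PriorParams,
    Scorer,
    contig_impact_scores,
    estimate_prior_from_lengths,
    trim_assembly,
)
from .simulate import (
    SimConfig,
    _random_seq,
    perturb_fission,
    perturb_indel,
    perturb_substitution,
    simulate_reads,
    simulate_transcriptome,
)
from .true_assembly import contigs_to_assembly, true_contigs


def _child_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Two-isoform ranking
# ---------------------------------------------------------------------------

def two_isoform_scores(seed: int) -> dict[str, float]:
    """Score three assemblies of a two-isoform gene's reads.

    A gene has two isoforms: the short one (1000 bases) is the first half of
    the long one (2000 bases).  5000 single-end reads of length 100 with
    0.01% sequencing error are simulated at a 90:10 short:long abundance
    ratio.  The candidate assemblies are the true two-isoform transcript
    set, the long isoform alone, and the short isoform alone.
    """
    rng = np.random.default_rng(seed)
    long_seq = _random_seq(rng, 2000)
    short_seq = long_seq[:1000]
    iso_short = SequenceRecord("iso_short", short_seq)
    iso_long = SequenceRecord("iso_long", long_seq)
    config = SimConfig(
        n_transcripts=2, N=5000, L=100, epsilon=1e-4, seed=_child_seed(seed, 1)
    )
    reads = simulate_reads([iso_short, iso_long], [0.9, 0.1], config)
    params = ModelParams(L=100, epsilon=1e-4)
    prior = estimate_prior_from_lengths([1000, 2000])
    scorer = Scorer(reads, params, prior)
    return {
        "both": scorer.score(Assembly([iso_short, iso_long])).total,
        "long_only": scorer.score(Assembly([iso_long])).total,
        "short_only": scorer.score(Assembly([iso_short])).total,
    }


def two_isoform_win_rate(seed: int, n_trials: int = 20) -> float:
    """Fraction of trials in which the true two-isoform assembly scores best."""
    wins = 0
    for t in range(n_trials):
        s = two_isoform_scores(_child_seed(seed, 100 + t))
        if s["both"] > s["long_only"] and s["both"] > s["short_only"]:
            wins += 1
    return wins / n_trials


# ---------------------------------------------------------------------------
# Random perturbation
# ---------------------------------------------------------------------------

def random_perturbation_experiment(
    seed: int,
    n_transcripts: int = 260,
    n_reads: int = 200_000,
    read_len: int = 76,
    strengths: Sequence[float] = (1e-4, 1e-3, 1e-2),
    types: Sequence[str] = ("substitution", "fission", "indel"),
    n_replicates: int = 50,
) -> dict:
    """Score randomly perturbed variants of a simulated ground truth.

    Returns the truth's normalized score, per-class normalized score lists,
    and per-class error rates (fraction of perturbed assemblies scoring
    above the truth).
    """
    config = SimConfig(
        n_transcripts=n_transcripts, N=n_reads, L=read_len,
        nb_r=2.0, nb_p=2.0 / 402.0, epsilon=0.005, seed=_child_seed(seed, 2),
    )
    transcripts, tau = simulate_transcriptome(config)
    reads = simulate_reads(transcripts, tau, config)
    contigs = true_contigs(reads, transcripts, w=0)
    truth = contigs_to_assembly(contigs)
    prior = estimate_prior_from_lengths([len(t) for t in transcripts])
    params = ModelParams(L=read_len, epsilon=config.epsilon)
    scorer = Scorer(reads, params, prior, exact_prior=False)
    truth_score = scorer.score(truth).normalized

    results: dict[str, dict[float, list[float]]] = {t: {} for t in types}
    for ti, ptype in enumerate(types):
        for si, strength in enumerate(strengths):
            scores = []
            for rep in range(n_replicates):
                pseed = _child_seed(seed, 3, ti, si, rep)
                if ptype == "substitution":
                    perturbed = perturb_substitution(truth, strength, pseed)
                elif ptype == "indel":
                    perturbed = perturb_indel(truth, strength, pseed)
                elif ptype == "fission":
                    perturbed = perturb_fission(contigs, strength, pseed)
                else:
                    raise ValueError(ptype)
                scores.append(scorer.score(perturbed).normalized)
            results[ptype][strength] = scores

    error_rates = {
        t: {s: float(np.mean([x > truth_score for x in v]))
            for s, v in results[t].items()}
        for t in types
    }
    means = {
        t: {s: float(np.mean(v)) for s, v in results[t].items()} for t in types
    }
    return {
        "truth_normalized": truth_score,
        "n_contigs": truth.M,
        "n_reads": n_reads,
        "scores": results,
        "means": means,
        "error_rates": error_rates,
    }


# ---------------------------------------------------------------------------
# Guided perturbation: true assemblies at increasing minimum overlap
# ---------------------------------------------------------------------------

def guided_perturbation_experiment(
    seed: int,
    n_transcripts: int = 40,
    n_reads: int = 30_000,
    read_len: int = 76,
    ws: Sequence[int] = (0, 1, 2, 5, 10, 25, 75),
) -> dict:
    """Score true assemblies built at a range of minimum overlap lengths.

    Returns per-w totals and uncorrected ML terms.  The full score should
    peak at small w (the ground truth end), whereas the ML term alone
    rewards the fragmented, duplicated assemblies produced at large w.
    """
    config = SimConfig(
        n_transcripts=n_transcripts, N=n_reads, L=read_len,
        nb_r=2.0, nb_p=2.0 / 402.0, epsilon=0.005, seed=_child_seed(seed, 4),
    )
    transcripts, tau = simulate_transcriptome(config)
    reads = simulate_reads(transcripts, tau, config)
    prior = estimate_prior_from_lengths([len(t) for t in transcripts])
    params = ModelParams(L=read_len, epsilon=config.epsilon)
    scorer = Scorer(reads, params, prior, exact_prior=False)
    totals: dict[int, float] = {}
    logliks: dict[int, float] = {}
    n_contigs: dict[int, int] = {}
    for w in ws:
        asm = contigs_to_assembly(true_contigs(reads, transcripts, w=w))
        bd = scorer.score(asm)
        totals[w] = bd.total
        logliks[w] = bd.loglik_uncorrected
        n_contigs[w] = asm.M
    return {"totals": totals, "logliks": logliks, "n_contigs": n_contigs}


# ---------------------------------------------------------------------------
# EM parameter recovery
# ---------------------------------------------------------------------------

def em_recovery_experiment(
    seed: int,
    n_transcripts: int = 8,
    n_reads: int = 5000,
    read_len: int = 50,
) -> dict:
    """Recover known mixture weights from simulated reads.

    Random transcripts share no homology, so alignments are unique and the
    EM estimate of each theta_i should match the read-sampling weight.
    """
    config = SimConfig(
        n_transcripts=n_transcripts, N=n_reads, L=read_len,
        nb_r=8.0, nb_p=8.0 / 508.0, epsilon=0.002, seed=_child_seed(seed, 5),
    )
    transcripts, tau = simulate_transcriptome(config)
    reads = simulate_reads(transcripts, tau, config)
    lengths = np.array([len(t) for t in transcripts], dtype=float)
    eff = lengths - read_len + 1
    weights = np.asarray(tau) * eff
    weights = weights / weights.sum()
    from .read_model import em_fit

    est = em_fit(reads, Assembly(list(transcripts)), ModelParams(L=read_len, epsilon=config.epsilon))
    err = np.abs(est.theta[1:] - weights)
    return {
        "max_abs_error": float(err.max()),
        "theta0": float(est.theta[0]),
        "true_weights": weights,
        "estimated": est.theta[1:],
    }


# ---------------------------------------------------------------------------
# Impact-based trimming
# ---------------------------------------------------------------------------

def trimming_experiment(
    seed: int,
    n_true: int = 10,
    n_junk: int = 5,
    n_reads: int = 20_000,
    read_len: int = 50,
) -> dict:
    """Trim an assembly of true contigs plus random junk by impact score."""
    config = SimConfig(
        n_transcripts=n_true, N=n_reads, L=read_len,
        nb_r=8.0, nb_p=8.0 / 408.0, epsilon=0.002, seed=_child_seed(seed, 6),
    )
    transcripts, tau = simulate_transcriptome(config)
    reads = simulate_reads(transcripts, tau, config)
    truth = contigs_to_assembly(true_contigs(reads, transcripts, w=0))
    rng = np.random.default_rng(_child_seed(seed, 7))
    junk = [
        SequenceRecord(f"junk{i}", _random_seq(rng, int(rng.integers(300, 500))))
        for i in range(n_junk)
    ]
    mixed = Assembly(list(truth.contigs) + junk)
    prior = estimate_prior_from_lengths([len(t) for t in transcripts])
    params = ModelParams(L=read_len, epsilon=config.epsilon)
    impacts = contig_impact_scores(reads, mixed, params, prior, exact_prior=False)
    trimmed = trim_assembly(mixed, impacts)
    kept = {c.id for c in trimmed}
    junk_removed = sum(1 for j in junk if j.id not in kept)
    true_removed = sum(1 for c in truth.contigs if c.id not in kept)

    aln_before = align_assembly_to_reference(mixed, transcripts)
    aln_after = align_assembly_to_reference(trimmed, transcripts) if trimmed.M else []
    _, _, f1_before = nucleotide_level_scores(aln_before, mixed, transcripts)
    if trimmed.M:
        _, _, f1_after = nucleotide_level_scores(aln_after, trimmed, transcripts)
    else:
        f1_after = 0.0
    return {
        "junk_removed": junk_removed,
        "true_removed": true_removed,
        "n_junk": n_junk,
        "n_true": truth.M,
        "impacts": impacts,
        "f1_before": f1_before,
        "f1_after": f1_after,
    }


# ---------------------------------------------------------------------------
# Correlation of the reference-free score with the KC score
# ---------------------------------------------------------------------------

def score_kc_correlation_experiment(
    seed: int,
    n_transcripts: int = 30,
    n_reads: int = 20_000,
    read_len: int = 76,
) -> dict:
    """Score a spread of assemblies of one read set by both measures.

    The assembly set covers the truth, perturbed variants of increasing
    strength, a junk-padded variant and an impoverished half-truth, so the
    two scores are compared across a wide quality range.
    """
    config = SimConfig(
        n_transcripts=n_transcripts, N=n_reads, L=read_len,
        nb_r=2.0, nb_p=2.0 / 402.0, epsilon=0.005, seed=_child_seed(seed, 8),
    )
    transcripts, tau = simulate_transcriptome(config)
    reads = simulate_reads(transcripts, tau, config)
    contigs = true_contigs(reads, transcripts, w=0)
    truth = contigs_to_assembly(contigs)
    rng = np.random.default_rng(_child_seed(seed, 9))

    assemblies: dict[str, Assembly] = {"truth": truth}
    for i, rate in enumerate((1e-3, 3e-3, 1e-2, 3e-2)):
        assemblies[f"sub_{rate:g}"] = perturb_substitution(
            truth, rate, _child_seed(seed, 10, i)
        )
        assemblies[f"indel_{rate:g}"] = perturb_indel(
            truth, rate, _child_seed(seed, 11, i)
        )
    for i, rate in enumerate((3e-3, 1e-2)):
        assemblies[f"fiss_{rate:g}"] = perturb_fission(
            contigs, rate, _child_seed(seed, 12, i)
        )
    junk = [
        SequenceRecord(f"junk{i}", _random_seq(rng, 400)) for i in range(10)
    ]
    assemblies["junky"] = Assembly(list(truth.contigs) + junk)
    half = list(truth.contigs)[: truth.M // 2]
    assemblies["half"] = Assembly(half)

    prior = estimate_prior_from_lengths([len(t) for t in transcripts])
    params = ModelParams(L=read_len, epsilon=config.epsilon)
    scorer = Scorer(reads, params, prior, exact_prior=False)
    names = sorted(assemblies)
    free_scores = [scorer.score(assemblies[n]).normalized for n in names]
    kc_scores = [
        kc_score(assemblies[n], transcripts, tau, n_reads, read_len)[0]
        for n in names
    ]
    from scipy import stats as sstats

    rho = float(sstats.spearmanr(free_scores, kc_scores).statistic)
    return {
        "names": names,
        "score": free_scores,
        "kc": kc_scores,
        "spearman": rho,
    }


# ---------------------------------------------------------------------------
# Monte-Carlo oracles for the prior and the coverage correction
# ---------------------------------------------------------------------------

def mc_contig_length_distribution(
    lam: float,
    prior: PriorParams,
    L: int,
    n_transcripts: int = 1_000_000,
    seed: int = 0,
    batch: int = 20_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the bag-of-contigs process literally.

    For each simulated transcript: draw its length from the negative
    binomial, occupy each valid start position independently with
    probability 1 - exp(-lam), form maximal runs whose consecutive occupied
    positions are at most L - w apart, and pool the run lengths (+ L).
    Returns (lengths, relative frequencies).
    """
    rng = np.random.default_rng(seed)
    q = -math.expm1(-lam)
    G = L - prior.w
    counts: dict[int, int] = {}
    done = 0
    while done < n_transcripts:
        b = min(batch, n_transcripts - done)
        done += b
        m = rng.negative_binomial(prior.nb_r, prior.nb_p, size=b)
        m = m[m >= L]
        if m.size == 0:
            continue
        V = m - L + 1
        vmax = int(V.max())
        grid = rng.random((m.size, vmax)) < q
        grid &= np.arange(vmax)[None, :] < V[:, None]
        rows, cols = np.nonzero(grid)
        if rows.size == 0:
            continue
        new_run = np.ones(rows.size, dtype=bool)
        same_row = rows[1:] == rows[:-1]
        close = cols[1:] - cols[:-1] <= G
        new_run[1:] = ~(same_row & close)
        run_id = np.cumsum(new_run) - 1
        first = np.zeros(run_id[-1] + 1, dtype=np.int64)
        last = np.zeros(run_id[-1] + 1, dtype=np.int64)
        first[run_id[np.nonzero(new_run)[0]]] = cols[new_run]
        np.maximum.at(last, run_id, cols)
        spans = last - first
        lens, freq = np.unique(spans + L, return_counts=True)
        for l_, c_ in zip(lens, freq):
            counts[int(l_)] = counts.get(int(l_), 0) + int(c_)
    lengths = np.array(sorted(counts))
    freqs = np.array([counts[int(l_)] for l_ in lengths], dtype=float)
    return lengths, freqs / freqs.sum()


def mc_coverage_prob(
    ell: int,
    lam: float,
    L: int,
    w: int = 0,
    n_replicates: int = 100_000,
    seed: int = 0,
) -> float:
    """Probability that Poisson read starts fully cover a contig.

    A replicate succeeds when a read starts at the first position, a read
    ends at the last position, and consecutive start positions are at most
    L - w apart.
    """
    if ell < L:
        return 0.0
    rng = np.random.default_rng(seed)
    q = -math.expm1(-lam)
    V = ell - L + 1
    G = L - w
    grid = rng.random((n_replicates, V)) < q
    ok = grid[:, 0] & grid[:, -1]
    if V > 1:
        idx = np.where(grid, np.arange(V)[None, :], -10 * V)
        prev = np.maximum.accumulate(idx, axis=1)
        gap_bad = (grid[:, 1:] & (np.arange(1, V)[None, :] - prev[:, :-1] > G)).any(axis=1)
        ok &= ~gap_bad
    return float(ok.mean())
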