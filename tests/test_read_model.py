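import math

import numpy as np
import pytest

from asmeval._encode import revcomp
from asmeval.read_model import (
    CandidateAlignment,
    ModelParams,
    align_reads,
    convert_theta_to_lambda,
    em_fit,
    posterior_alignment_probs,
    read_given_alignment_loglik,
)
from asmeval.records import Assembly, Read, ReadSet, SequenceRecord
from asmeval.simulate import _random_seq


def brute_force_alignments(reads, assembly, params):
    """Exhaustive window scan over every (contig, offset, strand)."""
    out = set()
    for read in reads:
        if any(ch not in "ACGT" for ch in read.seq):
            continue
        variants = [("+", read.seq)]
        if not params.strand_specific:
            variants.append(("-", revcomp(read.seq)))
        for ci, contig in enumerate(assembly, start=1):
            for start in range(len(contig) - params.L + 1):
                window = contig.seq[start : start + params.L]
                for strand, seq in variants:
                    mm = sum(
                        1 for a, b in zip(seq, window)
                        if a != b or b not in "ACGT"
                    )
                    if mm <= params.max_mismatches:
                        out.add((read.id, ci, start, strand, mm))
    return out


def mutate(rng, seq, n):
    chars = list(seq)
    for p in rng.choice(len(chars), size=n, replace=False):
        chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
    return "".join(chars)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("L,seed_len", [(76, 25), (30, 25), (20, 25)])
def test_alignment_matches_brute_force(seed, L, seed_len):
    """The seeded aligner finds exactly the brute-force alignment set."""
    rng = np.random.default_rng(seed)
    contigs = [
        SequenceRecord(f"c{i}", _random_seq(rng, int(n)))
        for i, n in enumerate(rng.integers(max(L, 40), 500, size=4))
    ]
    # a short contig exercises the exhaustive fallback path
    contigs.append(SequenceRecord("tiny", _random_seq(rng, max(L, 10))))
    assembly = Assembly(contigs)
    params = ModelParams(L=L, epsilon=0.01, seed_length=seed_len)
    reads = []
    for i in range(30):
        c = contigs[int(rng.integers(0, len(contigs)))]
        if len(c) < L:
            continue
        s = int(rng.integers(0, len(c) - L + 1))
        frag = c.seq[s : s + L]
        frag = mutate(rng, frag, int(rng.integers(0, 4)))  # up to 3 errors
        if rng.random() < 0.5:
            frag = revcomp(frag)
        reads.append(Read(f"r{i}", frag))
    reads.append(Read("unrelated", _random_seq(rng, L)))
    readset = ReadSet(reads)
    got = {
        (a.read_id, a.contig_index, a.start, a.strand, a.mismatches)
        for a in align_reads(readset, assembly, params)
        if a.contig_index > 0
    }
    assert got == brute_force_alignments(readset, assembly, params)


def test_every_read_gets_noise_pseudo_alignment(rng):
    assembly = Assembly([SequenceRecord("c", _random_seq(rng, 100))])
    readset = ReadSet([Read("r0", _random_seq(rng, 30))])
    alignments = align_reads(readset, assembly, ModelParams(L=30))
    assert alignments[0] == CandidateAlignment("r0", 0, 0, ".", 0)


def test_read_length_mismatch_is_error(rng):
    assembly = Assembly([SequenceRecord("c", _random_seq(rng, 100))])
    readset = ReadSet([Read("r0", "ACGT")])
    with pytest.raises(ValueError, match="read length"):
        align_reads(readset, assembly, ModelParams(L=30))


def test_emission_loglik_formulas(rng):
    # perfect strand-specific match on a contig of exactly read length
    eps = 0.01
    contig = SequenceRecord("c", _random_seq(rng, 8))
    read = Read("r", contig.seq)
    params = ModelParams(L=8, epsilon=eps, strand_specific=True)
    aln = CandidateAlignment("r", 1, 0, "+", 0)
    got = read_given_alignment_loglik(read, aln, Assembly([contig]), params)
    assert got == pytest.approx(8 * math.log(1 - eps))

    # uniform noise model, L=4
    params4 = ModelParams(L=4)
    noise = CandidateAlignment("r", 0, 0, ".", 0)
    got = read_given_alignment_loglik(Read("r", "ACGT"), noise, Assembly([contig]), params4)
    assert got == pytest.approx(4 * math.log(0.25))

    # mm=2, L=100, eps=0.01, ell=199, non-strand-specific: direct product
    contig199 = SequenceRecord("c199", _random_seq(rng, 199))
    read100 = Read("r100", contig199.seq[10:110])
    params100 = ModelParams(L=100, epsilon=0.01)
    aln2 = CandidateAlignment("r100", 1, 10, "+", 2)
    expected = math.log(
        (1 / (199 - 100 + 1)) * 0.5 * (0.99**98) * ((0.01 / 3) ** 2)
    )
    got = read_given_alignment_loglik(
        read100, aln2, Assembly([contig199]), params100
    )
    assert got == pytest.approx(expected, rel=1e-12)


def test_alignment_window_outside_contig_is_error(rng):
    contig = SequenceRecord("c", _random_seq(rng, 50))
    read = Read("r", contig.seq[:30])
    bad = CandidateAlignment("r", 1, 40, "+", 0)
    with pytest.raises(ValueError, match="outside"):
        read_given_alignment_loglik(read, bad, Assembly([contig]), ModelParams(L=30))


def make_simple_readset(rng, contig, n, L):
    reads = []
    for i in range(n):
        s = int(rng.integers(0, len(contig) - L + 1))
        reads.append(Read(f"r{i}", contig.seq[s : s + L]))
    return ReadSet(reads)


def test_em_degenerate_single_contig(rng):
    contig = SequenceRecord("c", _random_seq(rng, 300))
    readset = make_simple_readset(rng, contig, 50, 40)
    est = em_fit(readset, Assembly([contig]), ModelParams(L=40, epsilon=0.01))
    assert est.theta[0] < 1e-3
    assert est.theta[1] > 0.999


def test_em_two_contig_split_recovery(rng):
    c1 = SequenceRecord("c1", _random_seq(rng, 400))
    c2 = SequenceRecord("c2", _random_seq(rng, 400))
    reads = []
    for i in range(1000):
        c = c1 if i < 900 else c2
        s = int(rng.integers(0, len(c) - 40 + 1))
        reads.append(Read(f"r{i}", c.seq[s : s + 40]))
    est = em_fit(ReadSet(reads), Assembly([c1, c2]), ModelParams(L=40, epsilon=0.01))
    assert est.theta[1] == pytest.approx(0.9, abs=0.02)
    assert est.theta[2] == pytest.approx(0.1, abs=0.02)


def test_em_loglik_trace_non_decreasing(rng):
    # homologous contigs force real mixture iterations
    base = _random_seq(rng, 300)
    c1 = SequenceRecord("c1", base)
    c2 = SequenceRecord("c2", base[:200] + _random_seq(rng, 100))
    readset = make_simple_readset(rng, c1, 80, 50)
    est = em_fit(readset, Assembly([c1, c2]), ModelParams(L=50, epsilon=0.01))
    trace = np.array(est.loglik_trace)
    assert (np.diff(trace) >= -1e-8).all()
    assert est.n_iter >= 2


def test_posteriors_sum_to_one_and_split_symmetrically(rng):
    seq = _random_seq(rng, 200)
    twins = Assembly([SequenceRecord("a", seq), SequenceRecord("b", seq)])
    readset = make_simple_readset(rng, twins.contigs[0], 40, 50)
    params = ModelParams(L=50, epsilon=0.01)
    est = em_fit(readset, twins, params)
    alignments, probs = posterior_alignment_probs(readset, twins, est, params)
    per_read: dict[str, float] = {}
    for a, p in zip(alignments, probs):
        per_read[a.read_id] = per_read.get(a.read_id, 0.0) + p
    assert all(abs(total - 1.0) < 1e-9 for total in per_read.values())
    # identical contigs: each read's posterior splits equally
    for a, p in zip(alignments, probs):
        if a.contig_index > 0:
            assert p == pytest.approx(0.5, abs=1e-6)


def test_posterior_matches_hand_bayes_table(rng):
    """Three reads, two contigs: posterior equals the enumerated Bayes table."""
    c1 = SequenceRecord("c1", _random_seq(rng, 60))
    c2 = SequenceRecord("c2", _random_seq(rng, 90))
    assembly = Assembly([c1, c2])
    params = ModelParams(L=20, epsilon=0.01, strand_specific=True)
    reads = ReadSet(
        [
            Read("ra", c1.seq[5:25]),
            Read("rb", c2.seq[40:60]),
            Read("rc", c1.seq[10:30]),
        ]
    )
    est = em_fit(reads, assembly, params)
    alignments, probs = posterior_alignment_probs(reads, assembly, est, params)

    # independent brute-force Bayes computation
    def emit(read, aln):
        return read_given_alignment_loglik(read, aln, assembly, params)

    for read in reads:
        cands = [CandidateAlignment(read.id, 0, 0, ".", 0)] + [
            CandidateAlignment(*t)
            for t in sorted(brute_force_alignments(ReadSet([read]), assembly, params))
        ]
        weights = np.array(
            [est.theta[a.contig_index] * math.exp(emit(read, a)) for a in cands]
        )
        expected = weights / weights.sum()
        got = np.array(
            [p for a, p in zip(alignments, probs) if a.read_id == read.id]
        )
        assert got == pytest.approx(expected, abs=1e-9)


def test_convert_theta_to_lambda():
    assembly = Assembly([SequenceRecord("c", "A" * 100)])
    lam = convert_theta_to_lambda(np.array([0.9, 0.1]), assembly, 1000, 76)
    assert lam[0] == pytest.approx(100 / 177)  # ell + L + 1, not ell - L + 1
    lam0 = convert_theta_to_lambda(np.array([1.0, 0.0]), assembly, 1000, 76)
    assert lam0[0] == 0.0
    with pytest.raises(ValueError, match="sum"):
        convert_theta_to_lambda(np.array([0.9, 0.3]), assembly, 1000, 76)


def test_alignment_tsv_round_trip(tmp_path, rng):
    from asmeval.read_model import dump_alignments, load_alignments

    contig = SequenceRecord("c", _random_seq(rng, 120))
    readset = make_simple_readset(rng, contig, 5, 30)
    alignments = align_reads(readset, Assembly([contig]), ModelParams(L=30))
    path = tmp_path / "aln.tsv"
    dump_alignments(alignments, path)
    assert load_alignments(path) == alignments
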