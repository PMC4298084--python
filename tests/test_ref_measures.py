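import itertools

import numpy as np
import pytest

from asmeval._encode import revcomp
from asmeval.records import Assembly, PslAlignment, SequenceRecord
from asmeval.ref_measures import (
    LocalAlignment,
    align_assembly_to_reference,
    alignments_from_psl,
    contig_level_scores,
    kc_score,
    n50,
    nucleotide_level_scores,
)
from asmeval.simulate import _random_seq


@pytest.fixture
def reference(rng):
    return [SequenceRecord("ref1", _random_seq(rng, 1000))]


def test_identical_assembly_scores_one(reference):
    asm = Assembly([SequenceRecord("c1", reference[0].seq)])
    aln = align_assembly_to_reference(asm, reference)
    rec, pre, f1, pairs = contig_level_scores(aln, asm, reference)
    assert (rec, pre, f1) == (1.0, 1.0, 1.0)
    assert pairs == [("c1", "ref1")]
    n_rec, n_pre, n_f1 = nucleotide_level_scores(aln, asm, reference)
    assert (n_rec, n_pre, n_f1) == (1.0, 1.0, 1.0)


def test_two_partial_contigs_split_the_levels(reference):
    """Two perfect contigs covering 60% each: no contig-level credit, full
    nucleotide-level recall."""
    seq = reference[0].seq
    asm = Assembly(
        [SequenceRecord("a", seq[:600]), SequenceRecord("b", seq[400:])]
    )
    aln = align_assembly_to_reference(asm, reference)
    rec, _, _, _ = contig_level_scores(aln, asm, reference)
    assert rec == 0.0
    n_rec, n_pre, _ = nucleotide_level_scores(aln, asm, reference)
    assert n_rec == 1.0
    assert n_pre == 1.0


def test_redundant_contigs_match_once(reference):
    seq = reference[0].seq
    asm = Assembly([SequenceRecord(f"c{i}", seq) for i in range(3)])
    aln = align_assembly_to_reference(asm, reference)
    rec, pre, f1, pairs = contig_level_scores(aln, asm, reference)
    assert len(pairs) == 1
    assert rec == 1.0
    assert pre == pytest.approx(1 / 3)


def test_contig_scores_invariant_to_order_and_names(rng, reference):
    seq = reference[0].seq
    asm1 = Assembly([SequenceRecord("x", seq[:500]), SequenceRecord("y", seq)])
    asm2 = Assembly([SequenceRecord("q", seq), SequenceRecord("p", seq[:500])])
    s1 = contig_level_scores(
        align_assembly_to_reference(asm1, reference), asm1, reference
    )[:3]
    s2 = contig_level_scores(
        align_assembly_to_reference(asm2, reference), asm2, reference
    )[:3]
    assert s1 == s2


def test_unknown_alignment_id_is_error(reference):
    asm = Assembly([SequenceRecord("c1", reference[0].seq)])
    ghost = LocalAlignment(
        "ghost", "ref1", "+", 0, 10, 0, 10, 10, 0, 0,
        np.arange(10), np.arange(10),
    )
    with pytest.raises(ValueError, match="unknown assembly id"):
        contig_level_scores([ghost], asm, reference)


def brute_best_order_cover(alignments, sizes, side):
    """Max correct positions over all selection orders (first-come claims)."""
    best = 0
    for perm in itertools.permutations(alignments):
        claimed = {sid: np.zeros(n, dtype=bool) for sid, n in sizes.items()}
        total = 0
        for la in perm:
            sid = la.ref_id if side == "ref" else la.asm_id
            pos = la.ref_match_pos if side == "ref" else la.asm_match_pos
            total += int((~claimed[sid][pos]).sum())
            if side == "ref":
                claimed[sid][la.ref_start : la.ref_end] = True
            else:
                claimed[sid][la.asm_start : la.asm_end] = True
        best = max(best, total)
    return best


def naive_greedy(alignments, size):
    """Independent step-by-step replay of the marginal-contribution rule."""
    claimed = np.zeros(size, dtype=bool)
    pool = list(alignments)
    total = 0
    while pool:
        scored = []
        for la in pool:
            gain = sum(1 for p in la.ref_match_pos if not claimed[p])
            scored.append((gain, la.aligned_len, (la.asm_id, la.ref_id), la))
        scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
        gain, _, _, pick = scored[0]
        if gain <= 0:
            break
        total += gain
        claimed[pick.ref_start : pick.ref_end] = True
        pool.remove(pick)
    return total


def test_greedy_selection_on_small_instances(rng):
    """The vectorized greedy matches an independent naive replay of the
    marginal-contribution rule, and never beats the best selection order."""
    ref = [SequenceRecord("r", _random_seq(rng, 300))]
    asm = Assembly([SequenceRecord("c", _random_seq(rng, 300))])
    for trial in range(20):
        alignments = []
        for i in range(int(rng.integers(2, 5))):
            r0 = int(rng.integers(0, 200))
            ln = int(rng.integers(30, 100))
            a0 = int(rng.integers(0, 200))
            n_match = int(rng.integers(0, ln + 1))
            mpos = np.sort(rng.choice(ln, size=n_match, replace=False))
            alignments.append(
                LocalAlignment(
                    "c", "r", "+", a0, a0 + ln, r0, r0 + ln,
                    n_match, ln - n_match, 0, a0 + mpos, r0 + mpos,
                )
            )
        got_rec, _, _ = nucleotide_level_scores(alignments, asm, ref)
        assert got_rec == pytest.approx(naive_greedy(alignments, 300) / 300)
        best = brute_best_order_cover(alignments, {"r": 300}, "ref")
        assert got_rec <= best / 300 + 1e-12


def test_empty_assembly_scores_zero(reference):
    asm = Assembly([])
    assert nucleotide_level_scores([], asm, reference) == (0.0, 0.0, 0.0)


def test_reverse_complement_contig_aligns_minus_strand(reference):
    asm = Assembly([SequenceRecord("rc", revcomp(reference[0].seq))])
    aln = align_assembly_to_reference(asm, reference)
    assert any(a.strand == "-" and a.matches == 1000 for a in aln)
    rec, _, _, _ = contig_level_scores(aln, asm, reference)
    assert rec == 1.0


def test_planted_diverged_insert_is_recovered(rng, reference):
    """A 500-bp 98%-identity copy inside random sequence is found."""
    core = list(reference[0].seq[200:700])
    for p in rng.choice(500, size=10, replace=False):
        core[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[core[p]]
    contig = _random_seq(rng, 400) + "".join(core) + _random_seq(rng, 300)
    asm = Assembly([SequenceRecord("pl", contig)])
    aln = align_assembly_to_reference(asm, reference)
    hit = max(aln, key=lambda a: a.matches)
    assert hit.matches >= 485
    assert hit.matches / hit.aligned_len >= 0.95


def test_psl_and_internal_alignments_agree(rng, reference):
    seq = reference[0].seq
    asm = Assembly([SequenceRecord("c1", seq[100:600])])
    internal = align_assembly_to_reference(asm, reference)
    psl = PslAlignment(
        matches=500, misMatches=0, repMatches=0, nCount=0,
        qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
        strand="+", qName="c1", qSize=500, qStart=0, qEnd=500,
        tName="ref1", tSize=1000, tStart=100, tEnd=600,
        blockCount=1, blockSizes=(500,), qStarts=(0,), tStarts=(100,),
    )
    imported = alignments_from_psl([psl], asm, reference)
    s_int = contig_level_scores(internal, asm, reference)[:3]
    s_psl = contig_level_scores(imported, asm, reference)[:3]
    assert s_int == s_psl
    n_int = nucleotide_level_scores(internal, asm, reference)
    n_psl = nucleotide_level_scores(imported, asm, reference)
    assert n_int == pytest.approx(n_psl)


def test_psl_minus_strand_coordinates(rng):
    ref = [SequenceRecord("r", _random_seq(rng, 200))]
    contig = SequenceRecord("c", revcomp(ref[0].seq[50:150]))
    asm = Assembly([contig])
    psl = PslAlignment(
        matches=100, misMatches=0, repMatches=0, nCount=0,
        qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
        strand="-", qName="c", qSize=100, qStart=0, qEnd=100,
        tName="r", tSize=200, tStart=50, tEnd=150,
        blockCount=1, blockSizes=(100,), qStarts=(0,), tStarts=(50,),
    )
    (la,) = alignments_from_psl([psl], asm, ref)
    assert la.matches == 100
    assert la.mismatches == 0
    assert set(la.ref_match_pos) == set(range(50, 150))
    assert set(la.asm_match_pos) == set(range(0, 100))


# ---------------------------------------------------------------------------
# KC score
# ---------------------------------------------------------------------------

def test_kc_closed_forms(rng, reference):
    asm = Assembly([SequenceRecord("c1", reference[0].seq)])
    kc, wkr, icr = kc_score(asm, reference, [1.0], n_reads=100, read_len=100)
    assert wkr == pytest.approx(1.0)
    assert icr == pytest.approx(1000 / (100 * 100))
    assert kc == pytest.approx(wkr - icr)


def test_kc_weighted_disjoint_references(rng):
    r1 = SequenceRecord("r1", _random_seq(rng, 500))
    r2 = SequenceRecord("r2", _random_seq(rng, 500))
    # distinct random 500-mers share no 76-mers
    asm = Assembly([SequenceRecord("c", r1.seq)])
    kc, wkr, icr = kc_score(asm, [r1, r2], [0.9, 0.1], 100, 76)
    assert wkr == pytest.approx(0.9, abs=1e-9)


def test_kc_strand_handling(rng, reference):
    asm_rc = Assembly([SequenceRecord("rc", revcomp(reference[0].seq))])
    _, wkr_canon, _ = kc_score(asm_rc, reference, [1.0], 100, 76)
    assert wkr_canon == pytest.approx(1.0)
    _, wkr_ss, _ = kc_score(
        asm_rc, reference, [1.0], 100, 76, strand_specific=True
    )
    assert wkr_ss < 0.01


def test_kc_k_too_large_is_error(rng):
    ref = [SequenceRecord("r", _random_seq(rng, 50))]
    asm = Assembly([SequenceRecord("c", ref[0].seq)])
    with pytest.raises(ValueError, match="exceeds"):
        kc_score(asm, ref, [1.0], 100, 100, k=60)


def test_n50_examples():
    assert n50(Assembly.from_sequences(["A" * 10])) == 10
    assert n50(Assembly.from_sequences(["A", "C", "G", "T" * 97])) == 97
    assert n50(Assembly.from_sequences(["A" * 5, "C" * 4, "G" * 3, "T" * 2, "A"])) == 4
    with pytest.raises(ValueError):
        n50(Assembly([]))
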