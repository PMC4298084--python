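import itertools

import numpy as np
import pytest

from asmeval.fastio import encode_origin
from asmeval.read_model import ModelParams
from asmeval.records import Assembly, Origin, Read, ReadSet, SequenceRecord
from asmeval.simulate import _random_seq, six_read_layout
from asmeval.true_assembly import (
    contigs_to_assembly,
    estimate_true_assembly,
    true_contigs,
    true_scaffolds,
)


def read_at(tid, left, L, transcript, serial=0):
    origin = Origin(tid, left, left + L - 1, "+")
    return Read(
        encode_origin(serial, origin),
        transcript.seq[left - 1 : left + L - 1],
        origin=origin,
    )


def brute_force_true_contigs(reads, w):
    """All maximal (start, end) segments admitting a valid ordered read chain."""
    n = len(reads)
    ivs = [(r.origin.left, r.origin.right) for r in reads]
    reachable_ends = {}  # start read -> set of reachable end reads

    def ends_from(i, seen):
        out = {i}
        for j in range(n):
            if j in seen:
                continue
            if ivs[i][1] - ivs[j][0] + 1 >= w:
                out |= ends_from(j, seen | {j})
        return out

    segments = set()
    for i in range(n):
        for j in ends_from(i, {i}):
            segments.add((ivs[i][0], ivs[j][1]))
    segments = {(s, e) for s, e in segments if s <= e}
    maximal = {
        (s, e)
        for s, e in segments
        if not any(
            (s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in segments
        )
    }
    return sorted(maximal)


def test_six_read_layout_counts():
    transcripts, reads = six_read_layout()
    assert len(true_contigs(reads, transcripts, w=0)) == 2
    assert len(true_contigs(reads, transcripts, w=1)) == 3


def test_six_read_layout_covers_exactly_the_reads():
    transcripts, reads = six_read_layout()
    contigs = true_contigs(reads, transcripts, w=0)
    covered = set()
    for c in contigs:
        covered |= set(range(c.start, c.end + 1))
    read_cover = set()
    for r in reads:
        read_cover |= set(range(r.origin.left, r.origin.right + 1))
    assert covered == read_cover


@pytest.mark.parametrize("w", [0, 1, 3, 10])
def test_single_read_gives_its_own_segment(rng, w):
    t = SequenceRecord("t", _random_seq(rng, 100))
    r = read_at("t", 11, 20, t)
    (c,) = true_contigs([r], [t], w=w)
    assert (c.start, c.end) == (11, 30)
    assert c.seq == t.seq[10:30]
    assert c.supporting_reads == [r.id]


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("w", [0, 1, 5, 12])
def test_sweep_equals_brute_force(seed, w):
    """The sweep reproduces exhaustive verification of the chain conditions."""
    rng = np.random.default_rng(seed)
    L = 15
    t = SequenceRecord("t", _random_seq(rng, 120))
    reads = [
        read_at("t", int(left), L, t, serial=i)
        for i, left in enumerate(rng.integers(1, 120 - L + 1, size=8))
    ]
    got = [(c.start, c.end) for c in true_contigs(reads, [t], w=w)]
    assert sorted(got) == brute_force_true_contigs(reads, w)


@pytest.mark.parametrize("seed", range(4))
def test_contig_count_non_decreasing_in_w(seed):
    rng = np.random.default_rng(seed + 100)
    L = 20
    t = SequenceRecord("t", _random_seq(rng, 300))
    reads = [
        read_at("t", int(left), L, t, serial=i)
        for i, left in enumerate(rng.integers(1, 300 - L + 1, size=25))
    ]
    counts = [len(true_contigs(reads, [t], w=w)) for w in range(0, L + 1, 4)]
    assert counts == sorted(counts)


def test_w0_contigs_partition_covered_positions(rng):
    L = 20
    t = SequenceRecord("t", _random_seq(rng, 400))
    reads = [
        read_at("t", int(left), L, t, serial=i)
        for i, left in enumerate(rng.integers(1, 400 - L + 1, size=30))
    ]
    contigs = true_contigs(reads, [t], w=0)
    seen: dict[int, int] = {}
    for c in contigs:
        for p in range(c.start, c.end + 1):
            assert p not in seen, "w=0 contigs must not overlap"
            seen[p] = 1
    covered = set()
    for r in reads:
        covered |= set(range(r.origin.left, r.origin.right + 1))
    assert set(seen) == covered


def test_unknown_transcript_is_error(rng):
    t = SequenceRecord("t", _random_seq(rng, 50))
    r = read_at("t", 1, 10, t)
    with pytest.raises(ValueError, match="unknown transcript"):
        true_contigs([r], [SequenceRecord("other", "ACGT" * 10)], w=0)


# ---------------------------------------------------------------------------
# Scaffolds
# ---------------------------------------------------------------------------

def make_pair(tid, left1, left2, L, transcript, serial):
    return (
        read_at(tid, left1, L, transcript, serial=serial),
        read_at(tid, left2, L, transcript, serial=serial + 1000),
    )


def test_spanning_pair_yields_scaffold_with_gap_ns(rng):
    t = SequenceRecord("t", _random_seq(rng, 300))
    L = 20
    reads = [read_at("t", 1, L, t, 0), read_at("t", 91, L, t, 1)]
    contigs = true_contigs(reads, [t], w=0)
    assert len(contigs) == 2
    pair = make_pair("t", 1, 91, L, t, 0)
    (scaf,) = true_scaffolds(contigs, [pair])
    # gap between [1,20] and [91,110] is 70 uncovered positions
    assert scaf.seq == t.seq[0:20] + "N" * 70 + t.seq[90:110]


def test_no_pairs_scaffolds_equal_contigs(rng):
    t = SequenceRecord("t", _random_seq(rng, 200))
    reads = [read_at("t", 1, 20, t, 0), read_at("t", 100, 20, t, 1)]
    contigs = true_contigs(reads, [t], w=0)
    scaffolds = true_scaffolds(contigs, [])
    assert [s.seq for s in scaffolds] == [c.seq for c in contigs]


def test_scaffold_transitivity_via_components(rng):
    t = SequenceRecord("t", _random_seq(rng, 500))
    L = 20
    reads = [read_at("t", p, L, t, i) for i, p in enumerate((1, 101, 201))]
    contigs = true_contigs(reads, [t], w=0)
    assert len(contigs) == 3
    pairs = [make_pair("t", 1, 101, L, t, 0), make_pair("t", 101, 201, L, t, 10)]
    scaffolds = true_scaffolds(contigs, pairs)
    assert len(scaffolds) == 1


def test_mates_on_different_transcripts_is_error(rng):
    t1 = SequenceRecord("t1", _random_seq(rng, 100))
    t2 = SequenceRecord("t2", _random_seq(rng, 100))
    contigs = true_contigs(
        [read_at("t1", 1, 20, t1, 0), read_at("t2", 1, 20, t2, 1)], [t1, t2], w=0
    )
    bad_pair = (read_at("t1", 1, 20, t1, 2), read_at("t2", 1, 20, t2, 3))
    with pytest.raises(ValueError, match="different transcripts"):
        true_scaffolds(contigs, [bad_pair])


# ---------------------------------------------------------------------------
# Estimation from reads without trusted origins
# ---------------------------------------------------------------------------

def test_estimate_recovers_true_assembly_for_unique_reads(rng):
    transcripts = [
        SequenceRecord("ta", _random_seq(rng, 300)),
        SequenceRecord("tb", _random_seq(rng, 250)),
    ]
    L = 30
    reads = []
    serial = 0
    for t in transcripts:
        for left in range(1, len(t) - L + 2, 10):
            reads.append(read_at(t.id, left, L, t, serial))
            serial += 1
    readset = ReadSet(reads)
    params = ModelParams(L=L, epsilon=0.01)
    est = estimate_true_assembly(readset, transcripts, params, seed=5)
    truth = contigs_to_assembly(true_contigs(reads, transcripts, w=0))
    assert sorted(c.seq for c in est) == sorted(c.seq for c in truth)


def test_estimate_is_deterministic_given_seed(rng):
    transcripts = [SequenceRecord("t", _random_seq(rng, 500))]
    L = 30
    reads = [
        read_at("t", int(p), L, transcripts[0], i)
        for i, p in enumerate(np.random.default_rng(0).integers(1, 470, size=60))
    ]
    readset = ReadSet(reads)
    params = ModelParams(L=L, epsilon=0.01)
    a = estimate_true_assembly(readset, transcripts, params, seed=42)
    b = estimate_true_assembly(readset, transcripts, params, seed=42)
    assert [c.seq for c in a] == [c.seq for c in b]
    assert [c.id for c in a] == [c.id for c in b]
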