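"""Synthetic transcriptomes, reads with known origins, and perturbed assemblies.

The generators emulate the study conditions used to validate the scores:
transcript lengths are negative binomial, sequences uniform over {A,C,G,T},
relative abundances Dirichlet; reads are drawn from transcripts with
effective-length-weighted probability, uniform start, optional random
strand, and independent per-base substitution errors.  Each simulated read
records its true origin in its name.

Perturbation generators produce assemblies in the local neighbourhood of a
ground truth: per-base substitutions, fusions of contig pairs with collapse
of shared end sequence, fissions at read-merge points with duplication of
the overlapped segment, and short indels with geometric(mean 3) lengths.
All generators are pure functions of their inputs and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._encode import BASES, revcomp
from .fastio import encode_origin
from .records import Assembly, Origin, Read, ReadSet, SequenceRecord
from .true_assembly import TrueContig


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated data set."""

    n_transcripts: int
    N: int  # number of reads
    L: int  # read length
    nb_r: float = 2.0
    nb_p: float = 2.0 / 402.0  # transcript length NB, mean 400
    dirichlet_alpha: float = 1.0
    epsilon: float = 0.005
    strand_specific: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.n_transcripts, self.N, self.L) <= 0:
            raise ValueError("n_transcripts, N and L must be positive")
        if not (0 < self.nb_p < 1) or self.nb_r <= 0 or self.dirichlet_alpha <= 0:
            raise ValueError("invalid distribution parameters")


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation class: type, strength, seed."""

    type: str  # substitution | fusion | fission | indel
    strength: float  # rate per site / merge point; event count for fusion
    seed: int = 0

    def __post_init__(self):
        if self.type not in ("substitution", "fusion", "fission", "indel"):
            raise ValueError(f"unknown perturbation type {self.type!r}")
        if self.strength <= 0:
            raise ValueError("strength must be positive")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def simulate_transcriptome(
    config: SimConfig,
) -> tuple[list[SequenceRecord], np.ndarray]:
    """Random transcripts (NB lengths, uniform bases) and Dirichlet abundances."""
    rng = np.random.default_rng(config.seed)
    lengths = rng.negative_binomial(config.nb_r, config.nb_p, size=config.n_transcripts)
    lengths = np.maximum(lengths, config.L)
    transcripts = [
        SequenceRecord(f"t{i}", _random_seq(rng, int(n))) for i, n in enumerate(lengths)
    ]
    tau = rng.dirichlet(np.full(config.n_transcripts, config.dirichlet_alpha))
    return transcripts, tau


def simulate_reads(
    transcripts: Sequence[SequenceRecord],
    tau: Sequence[float],
    config: SimConfig,
) -> ReadSet:
    """Reads with true origins encoded in their names.

    Transcript choice is proportional to tau times effective length
    (ell - L + 1), so read starts are uniform within a transcript; strand is
    uniform unless strand-specific; substitution errors occur independently
    at rate epsilon.
    """
    rng = np.random.default_rng(config.seed + 1)
    L, N = config.L, config.N
    lengths = np.array([len(t) for t in transcripts])
    if (lengths < L).any():
        raise ValueError("every transcript must be at least one read long")
    eff = (lengths - L + 1).astype(float)
    weights = np.asarray(tau, dtype=float) * eff
    weights = weights / weights.sum()
    t_idx = rng.choice(len(transcripts), size=N, p=weights)
    starts = (rng.random(N) * eff[t_idx]).astype(np.int64)  # 0-based
    if config.strand_specific:
        strands = np.zeros(N, dtype=np.int8)
    else:
        strands = rng.integers(0, 2, size=N).astype(np.int8)

    reads: list[Read] = []
    for i in range(N):
        t = transcripts[int(t_idx[i])]
        s = int(starts[i])
        frag = t.seq[s : s + L]
        strand = "+" if strands[i] == 0 else "-"
        if strand == "-":
            frag = revcomp(frag)
        if config.epsilon > 0:
            n_err = rng.binomial(L, config.epsilon)
            if n_err:
                pos = rng.choice(L, size=n_err, replace=False)
                chars = list(frag)
                for p_ in pos:
                    old = chars[p_]
                    choices = [b for b in BASES if b != old]
                    chars[p_] = choices[int(rng.integers(0, 3))]
                frag = "".join(chars)
        origin = Origin(t.id, s + 1, s + L, strand)
        reads.append(Read(encode_origin(i, origin), frag, origin=origin))
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def perturb_substitution(assembly: Assembly, rate: float, seed: int) -> Assembly:
    """Independently substitute each base at the given rate (never to itself)."""
    if not (0 < rate < 1):
        raise ValueError("rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    contigs = []
    for c in assembly:
        chars = list(c.seq)
        hits = np.nonzero(rng.random(len(chars)) < rate)[0]
        for p in hits:
            old = chars[p]
            if old not in BASES:
                continue
            choices = [b for b in BASES if b != old]
            chars[p] = choices[int(rng.integers(0, 3))]
        contigs.append(SequenceRecord(c.id, "".join(chars)))
    return Assembly(contigs)


def perturb_indel(assembly: Assembly, rate: float, seed: int) -> Assembly:
    """Insertions/deletions at the given per-position rate.

    Indel lengths are geometric with mean 3 (support 1, 2, ...); insertions
    are random sequence; a deletion is truncated so it never removes an
    entire contig.
    """
    if not (0 < rate < 1):
        raise ValueError("rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    contigs = []
    for c in assembly:
        seq = c.seq
        hits = np.nonzero(rng.random(len(seq)) < rate)[0]
        # apply right-to-left so positions stay valid
        for p in hits[::-1]:
            length = int(rng.geometric(1.0 / 3.0))
            if rng.random() < 0.5:  # insertion
                seq = seq[: p + 1] + _random_seq(rng, length) + seq[p + 1 :]
            else:  # deletion
                length = min(length, len(seq) - 1)
                if length <= 0:
                    continue
                end = min(p + length, len(seq))
                seq = seq[:p] + seq[end:]
                if not seq:
                    seq = c.seq[:1]
        contigs.append(SequenceRecord(c.id, seq))
    return Assembly(contigs)


def _collapse_join(left: str, right: str) -> str:
    """Join two sequences, collapsing the longest shared suffix/prefix."""
    limit = min(len(left), len(right))
    for k in range(limit, 0, -1):
        if left[-k:] == right[:k]:
            return left + right[k:]
    return left + right


def perturb_fusion(assembly: Assembly, n_events: int, seed: int) -> Assembly:
    """Repeatedly join two randomly selected contigs head-to-tail.

    Shared sequence at the joined ends appears only once in the fused
    contig.  The contig count decreases by exactly n_events.
    """
    if n_events >= assembly.M:
        raise ValueError("cannot fuse more times than there are joinable contigs")
    rng = np.random.default_rng(seed)
    seqs = [c.seq for c in assembly]
    for _ in range(n_events):
        i, j = rng.choice(len(seqs), size=2, replace=False)
        i, j = int(i), int(j)
        merged = _collapse_join(seqs[i], seqs[j])
        keep = [s for idx, s in enumerate(seqs) if idx not in (i, j)]
        keep.append(merged)
        seqs = keep
    return Assembly.from_sequences(seqs, prefix="fused")


def perturb_fission(
    contigs: Sequence[TrueContig], rate: float, seed: int
) -> Assembly:
    """Split contigs at read-merge points, duplicating overlapped segments.

    Each position where two reads were merged in the ground truth is
    independently selected as a fission point at the given rate.  When the
    merged reads overlapped, the overlapping segment appears in both
    fragments after the split.  Requires the read layout (TrueContig form).
    """
    if not (0 < rate < 1):
        raise ValueError("rate must be in (0, 1)")
    if not contigs:
        raise ValueError("no contigs")
    if not all(isinstance(c, TrueContig) for c in contigs):
        raise ValueError("fission requires contigs carrying their read layout")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    for c in contigs:
        points = [
            (left, prev_right)
            for (left, prev_right) in c.merge_points
            if rng.random() < rate
        ]
        points.sort()
        frag_start = c.start
        for left, prev_right in points:
            # fragment ends at the rightmost coverage before the merge;
            # next fragment starts at the merged read's left end
            if prev_right < frag_start:
                continue
            seqs.append(c.seq[frag_start - c.start : prev_right - c.start + 1])
            frag_start = left
        seqs.append(c.seq[frag_start - c.start :])
    return Assembly.from_sequences(seqs, prefix="fiss")


def perturb(assembly, spec: PerturbationSpec) -> Assembly:
    """Apply one perturbation class (dispatch by spec.type)."""
    if spec.type == "substitution":
        return perturb_substitution(assembly, spec.strength, spec.seed)
    if spec.type == "indel":
        return perturb_indel(assembly, spec.strength, spec.seed)
    if spec.type == "fusion":
        return perturb_fusion(assembly, int(spec.strength), spec.seed)
    if spec.type == "fission":
        return perturb_fission(assembly, spec.strength, spec.seed)
    raise AssertionError


# ---------------------------------------------------------------------------
# Worked example: six reads on one transcript
# ---------------------------------------------------------------------------

def six_read_layout(seed: int = 7) -> tuple[list[SequenceRecord], list[Read]]:
    """One transcript and six origin-annotated reads.

    Reads 1-2 overlap, reads 2-3 are exactly adjacent (zero overlap), an
    uncovered gap separates reads 3 and 4, and reads 4-6 overlap.  The true
    assembly therefore has two contigs at minimum overlap length w = 0 and
    three at w = 1.
    """
    rng = np.random.default_rng(seed)
    L = 20
    transcript = SequenceRecord("tx", _random_seq(rng, 140))
    lefts = [1, 15, 35, 70, 80, 95]
    # read 2: [15,34]; read 3: [35,54] adjacent; gap 55..69 uncovered;
    # reads 4-6 overlap pairwise by >= 1
    reads = []
    for i, left in enumerate(lefts):
        origin = Origin("tx", left, left + L - 1, "+")
        seq = transcript.seq[left - 1 : left + L - 1]
        reads.append(Read(encode_origin(i, origin), seq, origin=origin))
    return [transcript], reads
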