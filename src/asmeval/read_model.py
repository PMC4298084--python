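"""Generative model of single-end RNA-Seq reads over an assembly.

The assembly's contigs are treated as a transcript set.  A read is generated
by a mixture: with weight theta_i (i >= 1) it is drawn from contig i --
uniform start over the ell_i - L + 1 valid positions, uniform strand choice
unless the protocol is strand-specific, and an independent per-base
substitution error at rate epsilon -- and with weight theta_0 it is drawn
base-by-base from a background ("noise") distribution.

The module provides exhaustive ungapped candidate alignment of reads to
contigs (exact-seed pigeonhole index with a brute-force fallback), the
per-alignment emission log-probability, EM estimation of the maximum
likelihood mixture weights Theta, posterior alignment probabilities, and the
conversion from Theta to per-contig expected read coverage Lambda, using
lambda_i = N * theta_i / (ell_i + L + 1).  The +L+1 (rather than -L+1)
denominator corrects for the fact that no reads can have started within L
bases of either side of the contig's reads, or the contig would have been
extended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._encode import encode
from .records import Assembly, ReadSet

logger = logging.getLogger(__name__)

_COMP_LUT = np.full(256, 255, dtype=np.uint8)
_COMP_LUT[:4] = [3, 2, 1, 0]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the read model.

    epsilon is the per-base substitution error probability (each of the 3
    alternative bases equally likely); background is the base distribution
    of the noise component.
    """

    L: int
    epsilon: float = 0.01
    strand_specific: bool = False
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    max_mismatches: int = 2
    seed_length: int = 25

    def __post_init__(self):
        if not (0 <= self.epsilon < 0.25):
            raise ValueError("epsilon must be in [0, 0.25)")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")


@dataclass(frozen=True)
class CandidateAlignment:
    """An ungapped candidate alignment; contig_index 0 is the noise component."""

    read_id: str
    contig_index: int  # 1-based; 0 = noise
    start: int  # 0-based start on the contig (0 for noise)
    strand: str  # '+' or '-' ('.' for noise)
    mismatches: int


@dataclass
class AbundanceEstimate:
    """EM-fitted mixture weights and the equivalent expected read coverages."""

    theta: np.ndarray  # theta_0..theta_M, sums to 1
    lam: np.ndarray  # lambda_1..lambda_M
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0


# ---------------------------------------------------------------------------
# Prepared (encoded) reads and assembly index
# ---------------------------------------------------------------------------

class PreparedReads:
    """Encoded read matrix plus precomputed seed k-mers, reusable across
    alignments of the same read set to many assemblies."""

    def __init__(self, reads: ReadSet, params: ModelParams):
        if reads.L != params.L:
            raise ValueError(f"read length {reads.L} != model L {params.L}")
        self.readset = reads
        self.n = len(reads)
        self.L = params.L
        mat = np.empty((self.n, self.L), dtype=np.uint8)
        for i, r in enumerate(reads):
            mat[i] = encode(r.seq)
        self.fwd = mat
        self.rev = _COMP_LUT[mat[:, ::-1]]
        self.valid = ~(mat > 3).any(axis=1)
        n_invalid = int((~self.valid).sum())
        if n_invalid:
            logger.info("aligner skipping %d reads containing non-ACGT bases", n_invalid)
        self._seed_cache: dict[tuple[int, int], np.ndarray] = {}

    def seeds(self, offset: int, k: int, strand: int) -> np.ndarray:
        key = (offset, k, strand)
        cached = self._seed_cache.get(key)
        if cached is not None:
            return cached
        mat = self.fwd if strand == 0 else self.rev
        window = mat[:, offset : offset + k].astype(np.uint64)
        powers = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
        vals = window @ powers
        self._seed_cache[key] = vals
        return vals


class AssemblyIndex:
    """Concatenated encoded contigs plus a sorted exact-seed k-mer index."""

    def __init__(self, assembly: Assembly, params: ModelParams):
        self.assembly = assembly
        self.L = params.L
        self.k = params.seed_length
        enc = [encode(c.seq) for c in assembly]
        lengths = np.array([e.shape[0] for e in enc], dtype=np.int64)
        self.lengths = lengths
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])[:-1]
        self.ends = self.offsets + lengths
        self.concat = (
            np.concatenate(enc) if enc else np.empty(0, dtype=np.uint8)
        )
        self.contig_of = np.repeat(np.arange(len(enc)), lengths)
        k = self.k
        kmer_chunks, pos_chunks = [], []
        for ci, e in enumerate(enc):
            if e.shape[0] < k:
                continue
            window = np.lib.stride_tricks.sliding_window_view(e, k)
            ok = ~(window > 3).any(axis=1)
            vals = window.astype(np.uint64) @ (
                np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
            )
            kmer_chunks.append(vals[ok])
            pos_chunks.append((np.nonzero(ok)[0] + self.offsets[ci]).astype(np.int64))
        if kmer_chunks:
            kmers = np.concatenate(kmer_chunks)
            gpos = np.concatenate(pos_chunks)
            order = np.argsort(kmers, kind="stable")
            self.kmers = kmers[order]
            self.gpos = gpos[order]
        else:
            self.kmers = np.empty(0, dtype=np.uint64)
            self.gpos = np.empty(0, dtype=np.int64)
        self.short_contigs = np.nonzero(lengths < k)[0]


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand [lo_i, hi_i) index ranges into (source index, flat position)."""
    counts = hi - lo
    total = int(counts.sum())
    src = np.repeat(np.arange(lo.size), counts)
    offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return src, lo[src] + offs


def _window_starts(lengths: np.ndarray, offsets: np.ndarray, L: int) -> np.ndarray:
    """All valid global window starts over the given contigs."""
    chunks = [
        np.arange(offsets[i], offsets[i] + lengths[i] - L + 1)
        for i in range(lengths.size)
        if lengths[i] >= L
    ]
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(chunks)


def align_read_arrays(
    prep: PreparedReads, index: AssemblyIndex, params: ModelParams
) -> dict[str, np.ndarray]:
    """All ungapped alignments with <= max_mismatches, as parallel arrays.

    Returns read_idx, contig (0-based), start (on contig), strand (0 = '+',
    1 = '-'), mismatches, sorted by (read_idx, contig, start, strand).  The
    noise pseudo-alignment is implicit and added by the EM machinery.
    """
    L, k = params.L, params.seed_length
    n_seeds = L // k
    strands = (0,) if params.strand_specific else (0, 1)

    use_seeding = (
        n_seeds >= params.max_mismatches + 1
        and index.kmers.size > 0
    )
    cand_read, cand_gstart, cand_strand = [], [], []
    if use_seeding:
        offsets = [i * k for i in range(n_seeds)]
        # pigeonhole: any alignment with <= max_mismatches leaves at least
        # one of the max_mismatches+1 non-overlapping seeds exact
        for strand in strands:
            for off in offsets:
                vals = prep.seeds(off, k, strand)
                lo = np.searchsorted(index.kmers, vals, side="left")
                hi = np.searchsorted(index.kmers, vals, side="right")
                lo, hi = lo[prep.valid], hi[prep.valid]
                ridx_all = np.nonzero(prep.valid)[0]
                src, flat = _expand_ranges(lo, hi)
                if src.size == 0:
                    continue
                gstart = index.gpos[flat] - off
                ridx = ridx_all[src]
                contig = index.contig_of[np.minimum(index.gpos[flat], index.concat.size - 1)]
                ok = (gstart >= index.offsets[contig]) & (
                    gstart + L <= index.ends[contig]
                )
                cand_read.append(ridx[ok])
                cand_gstart.append(gstart[ok])
                cand_strand.append(np.full(int(ok.sum()), strand, dtype=np.int8))
        # contigs shorter than the seed length: exhaustive scan
        scan_contigs = index.short_contigs
    else:
        scan_contigs = np.arange(index.lengths.size)

    if scan_contigs.size:
        starts = _window_starts(
            index.lengths[scan_contigs], index.offsets[scan_contigs], L
        )
        if starts.size:
            ridx_all = np.nonzero(prep.valid)[0]
            windows = index.concat[starts[:, None] + np.arange(L)]
            for strand in strands:
                mat = prep.fwd if strand == 0 else prep.rev
                # chunk reads to bound the (reads x windows) comparison
                for beg in range(0, ridx_all.size, 4096):
                    sel = ridx_all[beg : beg + 4096]
                    mm = (
                        (mat[sel][:, None, :] != windows[None, :, :])
                        .sum(axis=2)
                    )
                    ri, wi = np.nonzero(mm <= params.max_mismatches)
                    cand_read.append(sel[ri])
                    cand_gstart.append(starts[wi])
                    cand_strand.append(np.full(ri.size, strand, dtype=np.int8))

    if not cand_read:
        empty = np.empty(0, dtype=np.int64)
        return dict(
            read_idx=empty, contig=empty, start=empty,
            strand=empty.astype(np.int8), mismatches=empty,
        )

    read_idx = np.concatenate(cand_read)
    gstart = np.concatenate(cand_gstart)
    strand = np.concatenate(cand_strand)

    # dedupe candidates found via several seeds
    key = (read_idx.astype(np.uint64) * np.uint64(2 * max(index.concat.size, 1) + 2)
           + gstart.astype(np.uint64) * np.uint64(2) + strand.astype(np.uint64))
    _, uniq = np.unique(key, return_index=True)
    read_idx, gstart, strand = read_idx[uniq], gstart[uniq], strand[uniq]

    # verify: count mismatches over the full window
    windows = index.concat[gstart[:, None] + np.arange(L)]
    readmat = np.where(
        (strand == 0)[:, None], prep.fwd[read_idx], prep.rev[read_idx]
    )
    mismatches = (windows != readmat).sum(axis=1).astype(np.int64)
    keep = mismatches <= params.max_mismatches
    read_idx, gstart, strand, mismatches = (
        read_idx[keep], gstart[keep], strand[keep], mismatches[keep]
    )

    contig = index.contig_of[np.minimum(gstart, max(index.concat.size - 1, 0))]
    start = gstart - index.offsets[contig]
    order = np.lexsort((strand, start, contig, read_idx))
    return dict(
        read_idx=read_idx[order], contig=contig[order], start=start[order],
        strand=strand[order].astype(np.int8), mismatches=mismatches[order],
    )


def align_reads(
    reads: ReadSet, assembly: Assembly, params: ModelParams
) -> list[CandidateAlignment]:
    """All candidate alignments of each read, plus its noise pseudo-alignment.

    Deterministic order: reads in input order; within a read, the noise
    pseudo-alignment first, then (contig index, start, strand).
    """
    prep = PreparedReads(reads, params)
    index = AssemblyIndex(assembly, params)
    arr = align_read_arrays(prep, index, params)
    out: list[CandidateAlignment] = []
    by_read: dict[int, list[CandidateAlignment]] = {i: [] for i in range(len(reads))}
    for ri, ci, st, sd, mm in zip(
        arr["read_idx"], arr["contig"], arr["start"], arr["strand"], arr["mismatches"]
    ):
        by_read[int(ri)].append(
            CandidateAlignment(
                reads.reads[int(ri)].id, int(ci) + 1, int(st),
                "+" if sd == 0 else "-", int(mm),
            )
        )
    for i, read in enumerate(reads):
        out.append(CandidateAlignment(read.id, 0, 0, ".", 0))
        out.extend(by_read[i])
    return out


# ---------------------------------------------------------------------------
# Emission probabilities
# ---------------------------------------------------------------------------

def _noise_loglik(prep: PreparedReads, params: ModelParams) -> np.ndarray:
    """Per-read log-probability under the background noise model.

    Non-ACGT read bases contribute log(1/4).
    """
    lut = np.full(256, np.log(0.25))
    lut[:4] = np.log(np.asarray(params.background, dtype=float))
    return lut[prep.fwd].sum(axis=1)


def _alignment_loglik(
    mismatches: np.ndarray, contig_len: np.ndarray, params: ModelParams
) -> np.ndarray:
    """log P(read | alignment) for contig alignments (vectorized)."""
    L, eps = params.L, params.epsilon
    pos = -np.log((contig_len - L + 1).astype(float))
    orient = 0.0 if params.strand_specific else -np.log(2.0)
    if eps == 0.0:
        seq = np.where(mismatches == 0, 0.0, -np.inf)
    else:
        seq = (L - mismatches) * np.log1p(-eps) + mismatches * np.log(eps / 3.0)
    return pos + orient + seq


def read_given_alignment_loglik(
    read, alignment: CandidateAlignment, assembly: Assembly, params: ModelParams
) -> float:
    """log P(read | one candidate alignment) under the model."""
    if alignment.contig_index == 0:
        lut = np.full(256, np.log(0.25))
        lut[:4] = np.log(np.asarray(params.background, dtype=float))
        return float(lut[encode(read.seq)].sum())
    ell = len(assembly.contigs[alignment.contig_index - 1])
    L = params.L
    if alignment.start < 0 or alignment.start + L > ell:
        raise ValueError("alignment window outside contig")
    return float(
        _alignment_loglik(
            np.array([alignment.mismatches]), np.array([ell]), params
        )[0]
    )


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

class _EmWorkspace:
    """Alignment arrays augmented with the per-read noise row, ready for EM."""

    def __init__(self, prep: PreparedReads, index: AssemblyIndex, params: ModelParams,
                 arrays: Optional[dict] = None):
        self.prep = prep
        self.index = index
        self.params = params
        arr = arrays if arrays is not None else align_read_arrays(prep, index, params)
        n = prep.n
        noise_ll = _noise_loglik(prep, params)
        comp = np.concatenate([np.zeros(n, dtype=np.int64), arr["contig"] + 1])
        read_idx = np.concatenate([np.arange(n), arr["read_idx"]])
        ll = np.concatenate([
            noise_ll,
            _alignment_loglik(arr["mismatches"], index.lengths[arr["contig"]], params),
        ])
        order = np.lexsort((comp, read_idx))
        self.read_idx = read_idx[order]
        self.comp = comp[order]
        self.emit = ll[order]
        self.arr = arr
        starts = np.searchsorted(self.read_idx, np.arange(n), side="left")
        self.seg_starts = starts
        self.n = n
        self.M = index.lengths.size

    def per_read_logsumexp(self, logw: np.ndarray) -> np.ndarray:
        mx = np.maximum.reduceat(logw, self.seg_starts)
        mx = np.where(np.isfinite(mx), mx, 0.0)
        s = np.add.reduceat(np.exp(logw - mx[self.read_idx]), self.seg_starts)
        return mx + np.log(s)


def em_fit(
    reads: ReadSet,
    assembly: Assembly,
    params: ModelParams,
    tol: float = 1e-4,
    max_iter: int = 1000,
    seed: Optional[int] = None,
    workspace: Optional[_EmWorkspace] = None,
) -> AbundanceEstimate:
    """Maximum-likelihood mixture weights Theta by EM.

    Theta is initialized uniform over the M+1 components (deterministic;
    `seed` is reserved for optional random restarts and unused by default).
    Stops when the relative change in log-likelihood drops below `tol` or
    after `max_iter` iterations.  The log-likelihood trace is recorded and is
    non-decreasing.
    """
    if workspace is None:
        prep = PreparedReads(reads, params)
        index = AssemblyIndex(assembly, params)
        workspace = _EmWorkspace(prep, index, params)
    ws = workspace
    M, n = ws.M, ws.n
    with np.errstate(divide="ignore"):
        log_theta = np.full(M + 1, -np.log(M + 1))
    trace: list[float] = []
    loglik = -np.inf
    for it in range(max_iter):
        logw = log_theta[ws.comp] + ws.emit
        lse = ws.per_read_logsumexp(logw)
        if not np.isfinite(lse).all():
            bad = int(np.nonzero(~np.isfinite(lse))[0][0])
            raise ValueError(
                f"read {ws.prep.readset.reads[bad].id!r} has zero total probability"
            )
        new_loglik = float(lse.sum())
        trace.append(new_loglik)
        if it > 0 and abs(new_loglik - loglik) <= tol * abs(loglik):
            loglik = new_loglik
            break
        loglik = new_loglik
        resp = np.exp(logw - lse[ws.read_idx])
        theta = np.bincount(ws.comp, weights=resp, minlength=M + 1) / n
        with np.errstate(divide="ignore"):
            log_theta = np.log(theta)
    else:
        # report the likelihood of the parameters actually returned
        logw = log_theta[ws.comp] + ws.emit
        loglik = float(ws.per_read_logsumexp(logw).sum())
    theta = np.exp(log_theta)
    theta = theta / theta.sum()
    lam = convert_theta_to_lambda(theta, assembly, n, params.L)
    return AbundanceEstimate(
        theta=theta, lam=lam, loglik=loglik, loglik_trace=trace, n_iter=len(trace)
    )


def posterior_alignment_probs(
    reads: ReadSet,
    assembly: Assembly,
    estimate: AbundanceEstimate,
    params: ModelParams,
    workspace: Optional[_EmWorkspace] = None,
) -> tuple[list[CandidateAlignment], np.ndarray]:
    """Posterior probability of each candidate alignment given the fit.

    Returns the alignments in the deterministic :func:`align_reads` order
    (noise pseudo-alignment first within each read) and a parallel
    probability array; probabilities sum to 1 within each read.
    """
    if workspace is None:
        prep = PreparedReads(reads, params)
        index = AssemblyIndex(assembly, params)
        workspace = _EmWorkspace(prep, index, params)
    ws = workspace
    with np.errstate(divide="ignore"):
        logw = np.log(estimate.theta)[ws.comp] + ws.emit
    lse = ws.per_read_logsumexp(logw)
    post = np.exp(logw - lse[ws.read_idx])
    alignments = _describe(ws)
    return alignments, post


def _describe(ws: _EmWorkspace) -> list[CandidateAlignment]:
    n = ws.n
    arr = ws.arr
    # contig rows of ws are sorted identically to arr within each read
    out: list[CandidateAlignment] = []
    contig_ptr = 0
    for row in range(ws.read_idx.size):
        r = int(ws.read_idx[row])
        rid = ws.prep.readset.reads[r].id
        c = int(ws.comp[row])
        if c == 0:
            out.append(CandidateAlignment(rid, 0, 0, ".", 0))
        else:
            out.append(
                CandidateAlignment(
                    rid, c, int(arr["start"][contig_ptr]),
                    "+" if arr["strand"][contig_ptr] == 0 else "-",
                    int(arr["mismatches"][contig_ptr]),
                )
            )
            contig_ptr += 1
    return out


def convert_theta_to_lambda(
    theta: np.ndarray, assembly: Assembly, N: int, L: int
) -> np.ndarray:
    """lambda_i = N * theta_i / (ell_i + L + 1) for contigs i >= 1."""
    theta = np.asarray(theta, dtype=float)
    if abs(theta.sum() - 1.0) > 1e-6:
        raise ValueError("theta must sum to 1")
    lengths = np.asarray(assembly.lengths, dtype=float)
    return N * theta[1:] / (lengths + L + 1)


# ---------------------------------------------------------------------------
# Alignment caching (documented TSV)
# ---------------------------------------------------------------------------

def dump_alignments(alignments: Sequence[CandidateAlignment], path) -> None:
    """Write candidate alignments as TSV: read_id contig start strand mismatches."""
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tstart\tstrand\tmismatches\n")
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.contig_index}\t{a.start}\t{a.strand}\t{a.mismatches}\n")


def load_alignments(path) -> list[CandidateAlignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: missing alignment TSV header")
        for line in fh:
            rid, ci, st, sd, mm = line.rstrip("\n").split("\t")
            out.append(CandidateAlignment(rid, int(ci), int(st), sd, int(mm)))
    return out
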