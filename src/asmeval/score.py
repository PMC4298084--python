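"""Reference-free probabilistic assembly score.

The score of an assembly A given the reads D used to construct it is the
log joint probability log P(A, D) under a generative model, approximated as

    log P(A, D) ~ log P(D | A, Lambda_MLE)   (corrected likelihood)
                + log P(A | Lambda_MLE)      (assembly prior)
                - (1/2) (M + 1) log N        (BIC penalty)

with natural logarithms throughout.  Lambda_MLE is the per-contig expected
read coverage obtained by EM (see :mod:`asmeval.read_model`).

Assembly prior.  Each contig is generated independently.  A contig's parent
transcript has negative-binomially distributed length and uniform sequence;
reads start at each valid transcript position with Poisson(lambda) counts;
the contigs of the resulting true assembly (minimum overlap w) are pooled
into a bag, and the frequency of contig lengths in that bag defines
P(ell | lambda).  The prior is then

    P(A | Lambda) = (prod_i P(ell_i | lambda_i)) * (1/4)^(sum_i ell_i).

The length frequency is computed in closed form rather than by simulation:
with occupancy q = 1 - exp(-lambda) per valid start position, a contig of
length ell = d + L corresponds to a maximal run of occupied positions whose
consecutive gaps are at most G = L - w.  The expected number of such runs
factorizes into a run-interior connection probability u(d) (linear
recurrence), a boundary term T(n) (a self-correlation of capped geometric
tails) and the negative-binomial marginal over transcript lengths (a
convolution).  Tests validate this DP against a Monte-Carlo simulation of
the literal bag process.

Corrected likelihood.  The read model alone does not force the reads to
cover the assembly; the generative process therefore rejects read sets that
fail to cover every contig with pairwise overlaps >= w.  Conditioning on
acceptance divides the raw likelihood by P(C = 1), the product over contigs
of the probability of full coverage under Poisson read starts, computed
with the same connection recurrence.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

from .read_model import (
    AbundanceEstimate,
    AssemblyIndex,
    ModelParams,
    PreparedReads,
    _EmWorkspace,
    _noise_loglik,
    convert_theta_to_lambda,
    em_fit,
)
from .records import Assembly, ReadSet

LOG_QUARTER = math.log(0.25)


@dataclass(frozen=True)
class PriorParams:
    """Parameters of the assembly prior.

    nb_r / nb_p parameterize the negative binomial transcript-length
    distribution (scipy convention: number of successes r, success
    probability p, mean r(1-p)/p).  Defaults give mean 1500, a vertebrate
    transcriptome scale; re-estimate from a known transcript set with
    :func:`estimate_prior_from_lengths` when one is available.

    w is the minimum overlap length assumed by the model (0: the true
    assembly merges reads that overlap or are exactly adjacent).
    max_len truncates the length DP; None uses the NB 0.9999 quantile.
    """

    nb_r: float = 2.0
    nb_p: float = 2.0 / 1502.0
    w: int = 0
    max_len: Optional[int] = None

    def __post_init__(self):
        if self.nb_r <= 0 or not (0 < self.nb_p < 1):
            raise ValueError("require nb_r > 0 and 0 < nb_p < 1")
        if self.w < 0:
            raise ValueError("w must be >= 0")


def estimate_prior_from_lengths(lengths: Sequence[int], w: int = 0) -> PriorParams:
    """Method-of-moments negative binomial fit of transcript lengths."""
    arr = np.asarray(lengths, dtype=float)
    mean = arr.mean()
    var = arr.var()
    if var > mean:
        r = mean * mean / (var - mean)
    else:
        r = 1000.0  # near-Poisson lengths
    r = float(np.clip(r, 0.1, 1000.0))
    p = r / (r + mean)
    return PriorParams(nb_r=r, nb_p=p, w=w)


@dataclass
class ScoreBreakdown:
    """Components of the assembly score (natural logs)."""

    loglik_uncorrected: float
    log_correction: float  # log P(C=1) <= 0
    log_contig_length_prior: float
    log_assembly_size_prior: float
    bic_penalty: float
    total: float
    normalized: float
    M: int
    N: int
    theta: np.ndarray
    lam: np.ndarray


# ---------------------------------------------------------------------------
# Connection probability: the shared recurrence
# ---------------------------------------------------------------------------

def connection_prob(d_max: int, gap: int, q: float) -> np.ndarray:
    """u(d): probability that two occupied positions d apart are linked.

    Positions strictly between them are occupied independently with
    probability q; linked means consecutive occupied positions (endpoints
    included) are at most `gap` apart.  u(0) = 1.
    """
    if d_max < 0:
        return np.empty(0)
    u = np.zeros(d_max + 1)
    u[0] = 1.0
    if d_max == 0:
        return u
    if gap <= 0:
        return u
    one_minus = 1.0 - q
    x = np.zeros(d_max + 1)
    x[0] = 1.0
    top = min(gap, d_max)
    x[1 : top + 1] = one_minus ** np.arange(1, top + 1)
    c = q * one_minus ** np.arange(0, gap)  # c_j for j = 1..gap
    a = np.concatenate([[1.0], -c])
    return signal.lfilter([1.0], a, x)


# ---------------------------------------------------------------------------
# Contig length prior
# ---------------------------------------------------------------------------

def _effective_max_len(prior: PriorParams, L: int, need: int = 0) -> int:
    if prior.max_len is not None:
        base = prior.max_len
    else:
        base = int(stats.nbinom.ppf(0.9999, prior.nb_r, prior.nb_p))
    base = max(base, L + 1)
    if need > base:
        # round up so many assemblies reuse one cached support
        base = ((need // 1024) + 1) * 1024
    return base


@functools.lru_cache(maxsize=512)
def _length_distribution_cached(
    lam: float, nb_r: float, nb_p: float, w: int, max_len: int, L: int
) -> tuple:
    return _length_distribution(lam, nb_r, nb_p, w, max_len, L)


def _length_distribution(
    lam: float, nb_r: float, nb_p: float, w: int, max_len: int, L: int
) -> tuple:
    """pmf of contig length under the bag-of-contigs process.

    Returns (log_pmf, L): log_pmf[d] is log P(ell = L + d | lambda) for
    d = 0 .. max_len - L.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    q = -math.expm1(-lam)
    G = L - w
    if G < 0:
        raise ValueError("model w exceeds read length")
    n_max = max_len - L  # largest contig span
    d = np.arange(n_max + 1)

    u = connection_prob(n_max, G, q)

    # boundary factor: (1-q)^min(x, G) on each side of the run
    beta = (1.0 - q) ** np.minimum(d, G).astype(float)
    T = signal.fftconvolve(beta, beta)[: n_max + 1]
    T = np.maximum(T, 0.0)

    # negative binomial transcript-length marginal:
    # S(d) = sum_n P(m = L + d + n) T(n)
    m = np.arange(L, max_len + 1)
    nbtail = stats.nbinom.pmf(m, nb_r, nb_p)
    S = signal.fftconvolve(nbtail, T[::-1])[n_max : 2 * n_max + 1]
    S = np.maximum(S, 0.0)

    counts = u * S * q * q
    counts[0] = u[0] * S[0] * q  # single-start runs need only one occupied site
    total = counts.sum()
    if total <= 0:
        raise ValueError("degenerate length prior (no mass in support)")
    with np.errstate(divide="ignore"):
        log_pmf = np.log(counts) - np.log(total)
    return tuple(log_pmf), L


def contig_length_distribution(
    lam: float, prior: PriorParams, L: int, max_len: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Support (lengths) and pmf of the contig length prior at coverage lam."""
    ml = max_len if max_len is not None else _effective_max_len(prior, L)
    log_pmf, _ = _length_distribution_cached(
        float(lam), prior.nb_r, prior.nb_p, prior.w, ml, L
    )
    log_pmf = np.asarray(log_pmf)
    lengths = np.arange(L, L + log_pmf.size)
    return lengths, np.exp(log_pmf)


def contig_length_prior(
    ell: int, lam: float, prior: PriorParams, L: int, max_len: Optional[int] = None
) -> float:
    """log P(contig length = ell | coverage lam) under the bag process."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if ell < L:
        return -np.inf
    ml = max_len if max_len is not None else _effective_max_len(prior, L, need=ell)
    if ell > ml:
        return -np.inf
    log_pmf, _ = _length_distribution_cached(
        float(lam), prior.nb_r, prior.nb_p, prior.w, ml, L
    )
    return float(log_pmf[ell - L])


# interpolated lookup on a geometric lambda grid, for scoring many contigs
_GRID_PER_DECADE = 48


def _grid_index(lam: float) -> float:
    return math.log10(lam) * _GRID_PER_DECADE


def _length_prior_interp(
    ells: np.ndarray, lams: np.ndarray, prior: PriorParams, L: int, max_len: int
) -> np.ndarray:
    """log P(ell_i | lambda_i) for many contigs, interpolating in log lambda."""
    out = np.empty(ells.size)
    g = np.array([_grid_index(l) for l in lams])
    lo = np.floor(g).astype(int)
    frac = g - lo
    cache: dict[int, np.ndarray] = {}

    def dist(gi: int) -> np.ndarray:
        if gi not in cache:
            lam = 10.0 ** (gi / _GRID_PER_DECADE)
            log_pmf, _ = _length_distribution_cached(
                lam, prior.nb_r, prior.nb_p, prior.w, max_len, L
            )
            cache[gi] = np.asarray(log_pmf)
        return cache[gi]

    for i in range(ells.size):
        d = int(ells[i]) - L
        lo_lp = dist(int(lo[i]))[d]
        hi_lp = dist(int(lo[i]) + 1)[d]
        if np.isfinite(lo_lp) and np.isfinite(hi_lp):
            out[i] = (1 - frac[i]) * lo_lp + frac[i] * hi_lp
        else:
            out[i] = contig_length_prior(int(ells[i]), float(lams[i]), prior, L, max_len)
    return out


# ---------------------------------------------------------------------------
# Assembly prior, coverage correction, BIC
# ---------------------------------------------------------------------------

def lambda_floor(ell: int, L: int) -> float:
    """Floor for a contig's coverage: one expected read over its positions."""
    return 1.0 / (ell + L + 1)


def assembly_prior(
    assembly: Assembly,
    lam_vector: Sequence[float],
    prior: PriorParams,
    L: int,
    exact: bool = True,
) -> tuple[float, float]:
    """(log contig-length prior, log assembly-size prior) of an assembly.

    Contigs with non-positive coverage are floored at lambda_min =
    1/(ell+L+1).  The empty assembly has prior 0 (empty product).
    """
    if assembly.M == 0:
        return 0.0, 0.0
    ells = np.asarray(assembly.lengths)
    lams = np.asarray(lam_vector, dtype=float)
    floors = np.array([lambda_floor(int(e), L) for e in ells])
    lams = np.maximum(lams, floors)
    max_len = _effective_max_len(prior, L, need=int(ells.max()))
    if exact:
        length_term = sum(
            contig_length_prior(int(e), float(l), prior, L, max_len)
            for e, l in zip(ells, lams)
        )
    else:
        length_term = float(_length_prior_interp(ells, lams, prior, L, max_len).sum())
    size_term = float(ells.sum()) * LOG_QUARTER
    return float(length_term), size_term


def coverage_prob(ell: int, lam: float, L: int, w: int = 0) -> float:
    """log P(a contig of length ell is fully covered with overlaps >= w).

    Read starts are Poisson(lam) per valid position; coverage requires a
    start at the first position, a read ending at the last position, and
    consecutive starts at most L - w apart.
    """
    if ell < L:
        return -np.inf
    if lam <= 0:
        return -np.inf
    q = -math.expm1(-lam)
    V = ell - L + 1
    if V == 1:
        return math.log(q)
    G = L - w
    u = connection_prob(V - 1, G, q)[V - 1]
    if u <= 0:
        return -np.inf
    return 2 * math.log(q) + math.log(u)


def coverage_correction(
    assembly: Assembly,
    lam_vector: Sequence[float],
    params: ModelParams,
    w: int = 0,
) -> float:
    """log P(C=1): every contig fully covered with pairwise overlaps >= w."""
    return float(
        sum(
            coverage_prob(int(e), float(l), params.L, w)
            for e, l in zip(assembly.lengths, lam_vector)
        )
    )


def bic_penalty(M: int, N: int) -> float:
    """(1/2)(M+1) ln N: one coverage parameter per contig plus the noise rate."""
    if M < 0 or N < 1:
        raise ValueError("require M >= 0 and N >= 1")
    return 0.5 * (M + 1) * math.log(N)


# ---------------------------------------------------------------------------
# Full score
# ---------------------------------------------------------------------------

class Scorer:
    """Scores many assemblies of one read set, reusing the encoded reads."""

    def __init__(
        self,
        reads: ReadSet,
        params: ModelParams,
        prior: PriorParams,
        exact_prior: bool = False,
        em_tol: float = 1e-4,
        em_max_iter: int = 1000,
    ):
        self.params = params
        self.prior = prior
        self.exact_prior = exact_prior
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.prep = PreparedReads(reads, params)
        self.readset = reads
        self._noise_ll = _noise_loglik(self.prep, params)
        self.null_total = float(self._noise_ll.sum()) - bic_penalty(0, reads.N)

    def score(self, assembly: Assembly, details: bool = False):
        params, prior = self.params, self.prior
        N, L = self.readset.N, params.L
        if assembly.M == 0:
            bd = ScoreBreakdown(
                loglik_uncorrected=float(self._noise_ll.sum()),
                log_correction=0.0,
                log_contig_length_prior=0.0,
                log_assembly_size_prior=0.0,
                bic_penalty=bic_penalty(0, N),
                total=self.null_total,
                normalized=0.0,
                M=0,
                N=N,
                theta=np.array([1.0]),
                lam=np.empty(0),
            )
            return (bd, None) if details else bd
        index = AssemblyIndex(assembly, params)
        ws = _EmWorkspace(self.prep, index, params)
        est = em_fit(
            self.readset, assembly, params,
            tol=self.em_tol, max_iter=self.em_max_iter, workspace=ws,
        )
        ells = np.asarray(assembly.lengths)
        floors = 1.0 / (ells + L + 1)
        lam = np.maximum(est.lam, floors)

        # contigs shorter than a read are impossible under the bag process;
        # clamp their length to L in the length-prior and coverage terms so
        # they pay the prior and BIC finitely instead of voiding the score
        ells_model = np.maximum(ells, L)
        max_len = _effective_max_len(prior, L, need=int(ells_model.max()))
        if self.exact_prior:
            log_len_prior = float(
                sum(
                    contig_length_prior(int(e), float(l), prior, L, max_len)
                    for e, l in zip(ells_model, lam)
                )
            )
        else:
            log_len_prior = float(
                _length_prior_interp(ells_model, lam, prior, L, max_len).sum()
            )
        log_size_prior = float(ells.sum()) * LOG_QUARTER
        log_corr = float(
            sum(
                coverage_prob(int(e), float(l), L, prior.w)
                for e, l in zip(ells_model, lam)
            )
        )
        bic = bic_penalty(assembly.M, N)
        total = est.loglik - log_corr + log_len_prior + log_size_prior - bic
        bd = ScoreBreakdown(
            loglik_uncorrected=est.loglik,
            log_correction=log_corr,
            log_contig_length_prior=log_len_prior,
            log_assembly_size_prior=log_size_prior,
            bic_penalty=bic,
            total=total,
            normalized=total - self.null_total,
            M=assembly.M,
            N=N,
            theta=est.theta,
            lam=lam,
        )
        if details:
            return bd, _ScoreDetails(self, assembly, ws, est, lam)
        return bd


class _ScoreDetails:
    """Per-read and per-contig internals shared by the impact computation."""

    def __init__(self, scorer: Scorer, assembly: Assembly, ws, est, lam):
        self.scorer = scorer
        self.assembly = assembly
        self.ws = ws
        self.est = est
        self.lam = lam
        with np.errstate(divide="ignore"):
            logw = np.log(est.theta)[ws.comp] + ws.emit
        self.read_ll = ws.per_read_logsumexp(logw)
        self.post = np.exp(logw - self.read_ll[ws.read_idx])


def score_assembly(
    reads: ReadSet,
    assembly: Assembly,
    params: ModelParams,
    prior: PriorParams,
    exact_prior: bool = True,
    em_tol: float = 1e-4,
) -> ScoreBreakdown:
    """Score one assembly against the reads used to construct it."""
    return Scorer(
        reads, params, prior, exact_prior=exact_prior, em_tol=em_tol
    ).score(assembly)


def contig_impact_scores(
    reads: ReadSet,
    assembly: Assembly,
    params: ModelParams,
    prior: PriorParams,
    exact_prior: bool = True,
    em_tol: float = 1e-4,
    scorer: Optional[Scorer] = None,
) -> np.ndarray:
    """Per-contig impact: support for "contig i is true" over "its reads are noise".

    impact(i) is the contig's additive contribution to log P(A, D) minus the
    log-probability of its reads under the noise component.  With disjoint
    read support it equals the change in the full score when contig i is
    dropped and its reads fall back to noise.
    """
    if scorer is None:
        scorer = Scorer(
            reads, params, prior, exact_prior=exact_prior, em_tol=em_tol
        )
    bd, det = scorer.score(assembly, details=True)
    ws, est = det.ws, det.est
    N, L = reads.N, params.L
    theta = est.theta
    M = assembly.M
    # posterior-weighted (loglik - noise - log reallocated noise weight)
    noise_ll = scorer._noise_ll
    per_read_gain = det.read_ll - noise_ll  # over all reads, indexed by read
    contrib = np.zeros(M + 1)
    np.add.at(contrib, ws.comp, det.post * per_read_gain[ws.read_idx])
    impacts = np.empty(M)
    for i in range(1, M + 1):
        th_new_noise = theta[0] + theta[i]
        reads_term = contrib[i]
        if th_new_noise > 0:
            reads_term -= N * theta[i] * math.log(th_new_noise)
            if theta[0] > 0:
                reads_term += N * theta[0] * (
                    math.log(theta[0]) - math.log(th_new_noise)
                )
        ell = assembly.lengths[i - 1]
        ell_model = max(ell, L)  # same clamp as the full score
        lam_i = det.lam[i - 1]
        max_len = _effective_max_len(prior, L, need=int(max(max(assembly.lengths), L)))
        if scorer.exact_prior:
            lp = contig_length_prior(ell_model, float(lam_i), prior, L, max_len)
        else:
            lp = float(
                _length_prior_interp(
                    np.array([ell_model]), np.array([lam_i]), prior, L, max_len
                )[0]
            )
        impacts[i - 1] = (
            reads_term
            - coverage_prob(ell_model, float(lam_i), L, prior.w)
            + lp
            + ell * LOG_QUARTER
            - 0.5 * math.log(N)
        )
    return impacts


def trim_assembly(assembly: Assembly, impacts: Sequence[float]) -> Assembly:
    """Drop contigs with negative impact, preserving order."""
    impacts = np.asarray(impacts, dtype=float)
    if impacts.size != assembly.M:
        raise ValueError("impacts do not match assembly")
    kept = [c for c, s in zip(assembly.contigs, impacts) if s >= 0]
    return Assembly(kept)
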