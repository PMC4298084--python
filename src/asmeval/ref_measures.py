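"""Reference-based assembly accuracy measures.

Given an assembly and a set of reference sequences (full-length transcripts
or an estimated true assembly), this module computes:

* contig-level recall / precision / F1 -- a reference sequence is correctly
  recovered when at least 99% of its non-N sequence is identical to the
  assembly sequence it aligns to (and vice versa) and the alignment's
  inserted plus deleted bases are at most 1% of the shorter non-N length;
  matched pairs form a bipartite graph whose maximum-cardinality matching
  gives the counts;
* nucleotide-level recall / precision / F1 -- per-base credit under a greedy
  selection of alignments in order of marginal contribution, each position
  assigned at most one alignment;
* the k-mer compression score KC = WKR - ICR, where WKR is the
  abundance-weighted fraction of reference k-mers present in the assembly
  and ICR = |A| / (N L) is the assembly size over the total read bases;
* N50 and related size statistics.

Local alignments come either from BLAT PSL files or from the internal
seed-and-extend aligner (exact seed clustering on diagonals, ungapped X-drop
extension, banded global alignment of the clustered segments via edlib).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import networkx as nx
import numpy as np

from ._encode import revcomp
from .records import Assembly, PslAlignment, SequenceRecord
from .read_model import ModelParams, em_fit
from .records import ReadSet


@dataclass
class LocalAlignment:
    """A local alignment between one assembly and one reference sequence.

    Coordinates are 0-based half-open on the forward strands of both
    sequences.  `matches` counts aligned columns with identical non-N bases;
    `*_match_pos` hold the forward-strand coordinates of those columns.
    """

    asm_id: str
    ref_id: str
    strand: str
    asm_start: int
    asm_end: int
    ref_start: int
    ref_end: int
    matches: int
    mismatches: int
    indel_bases: int
    asm_match_pos: np.ndarray
    ref_match_pos: np.ndarray

    @property
    def aligned_len(self) -> int:
        return self.matches + self.mismatches + self.indel_bases


@dataclass
class EvalReport:
    contig_recall: float
    contig_precision: float
    contig_f1: float
    nucleotide_recall: float
    nucleotide_precision: float
    nucleotide_f1: float
    matched_pairs: list[tuple[str, str]]


def f1_score(recall: float, precision: float) -> float:
    if recall + precision == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)


def _non_n_length(seq: str) -> int:
    return len(seq) - seq.count("N")


# ---------------------------------------------------------------------------
# Internal local aligner
# ---------------------------------------------------------------------------

def _walk_cigar(
    cigar: str, qseq: str, tseq: str, q0: int, t0: int
) -> tuple[int, int, int, list[int], list[int]]:
    """Walk an extended cigar, counting identical non-N columns."""
    matches = mismatches = indels = 0
    qpos, tpos = q0, t0
    q_hit: list[int] = []
    t_hit: list[int] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            for _ in range(n):
                a, b = qseq[qpos], tseq[tpos]
                if a == b and a != "N":
                    matches += 1
                    q_hit.append(qpos)
                    t_hit.append(tpos)
                else:
                    mismatches += 1
                qpos += 1
                tpos += 1
        elif ch == "I":  # consumes query
            indels += n
            qpos += n
        elif ch == "D":  # consumes target
            indels += n
            tpos += n
        else:
            raise ValueError(f"unexpected cigar op {ch!r}")
    return matches, mismatches, indels, q_hit, t_hit


def _xdrop_extend(q: str, t: str, qi: int, ti: int, step: int, xdrop: int = 15):
    """Greedy ungapped extension from (qi, ti) in the given direction."""
    score = best = 0
    best_steps = 0
    steps = 0
    while 0 <= qi < len(q) and 0 <= ti < len(t):
        if q[qi] == t[ti] and q[qi] != "N":
            score += 1
        else:
            score -= 3
        steps += 1
        if score > best:
            best = score
            best_steps = steps
        if score < best - xdrop:
            break
        qi += step
        ti += step
    return best_steps


def align_assembly_to_reference(
    assembly: Assembly,
    reference: Sequence[SequenceRecord],
    seed_len: int = 16,
    max_diag_drift: int = 40,
    max_seed_gap: int = 200,
    min_matches: int = 30,
    min_identity: float = 0.7,
) -> list[LocalAlignment]:
    """Seed-and-extend local alignments of assembly sequences to references.

    Exact seed hits are clustered by diagonal, extended ungapped with an
    X-drop rule, and the clustered segments are aligned globally with edlib
    to obtain exact match/mismatch/indel counts and per-column coordinates.
    Both strands are searched.  Alignments with fewer than `min_matches`
    identical bases or aligned identity below `min_identity` are discarded.
    """
    # seed index over the references
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, ref in enumerate(reference):
        s = ref.seq
        for p in range(len(s) - seed_len + 1):
            kmer = s[p : p + seed_len]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((ri, p))

    out: list[LocalAlignment] = []
    for contig in assembly:
        for strand in ("+", "-"):
            qseq = contig.seq if strand == "+" else revcomp(contig.seq)
            hits: dict[int, list[tuple[int, int]]] = {}
            for p in range(len(qseq) - seed_len + 1):
                kmer = qseq[p : p + seed_len]
                if "N" in kmer:
                    continue
                for ri, rp in index.get(kmer, ()):
                    hits.setdefault(ri, []).append((rp - p, p))
            for ri, hlist in hits.items():
                tseq = reference[ri].seq
                hlist.sort()
                clusters: list[list[tuple[int, int]]] = []
                for diag, qp in hlist:
                    placed = False
                    for cl in clusters:
                        if abs(diag - cl[-1][0]) <= max_diag_drift and (
                            abs(qp - cl[-1][1]) <= max_seed_gap
                        ):
                            cl.append((diag, qp))
                            placed = True
                            break
                    if not placed:
                        clusters.append([(diag, qp)])
                for cl in clusters:
                    qps = [qp for _, qp in cl]
                    diags = [d for d, _ in cl]
                    q0, q1 = min(qps), max(qps) + seed_len
                    t0 = q0 + min(diags)
                    t1 = q1 + max(diags)
                    t0, t1 = max(t0, 0), min(t1, len(tseq))
                    if t1 <= t0:
                        continue
                    ext_l = min(
                        _xdrop_extend(qseq, tseq, q0 - 1, t0 - 1, -1), q0, t0
                    )
                    ext_r = min(
                        _xdrop_extend(qseq, tseq, q1, t1, +1),
                        len(qseq) - q1,
                        len(tseq) - t1,
                    )
                    q0e, q1e = q0 - ext_l, q1 + ext_r
                    t0e, t1e = t0 - ext_l, t1 + ext_r
                    res = edlib.align(
                        qseq[q0e:q1e], tseq[t0e:t1e], mode="NW", task="path"
                    )
                    m, mm, ind, q_hit, t_hit = _walk_cigar(
                        res["cigar"], qseq, tseq, q0e, t0e
                    )
                    if m < min_matches:
                        continue
                    if m / max(m + mm + ind, 1) < min_identity:
                        continue
                    if strand == "+":
                        asm_pos = np.array(q_hit, dtype=np.int64)
                        a0, a1 = q0e, q1e
                    else:
                        n = len(contig.seq)
                        asm_pos = n - 1 - np.array(q_hit, dtype=np.int64)
                        a0, a1 = n - q1e, n - q0e
                    out.append(
                        LocalAlignment(
                            asm_id=contig.id,
                            ref_id=reference[ri].id,
                            strand=strand,
                            asm_start=a0,
                            asm_end=a1,
                            ref_start=t0e,
                            ref_end=t1e,
                            matches=m,
                            mismatches=mm,
                            indel_bases=ind,
                            asm_match_pos=asm_pos,
                            ref_match_pos=np.array(t_hit, dtype=np.int64),
                        )
                    )
    # deduplicate identical spans found through several clusters
    seen = {}
    for la in out:
        key = (la.asm_id, la.ref_id, la.strand, la.asm_start, la.asm_end,
               la.ref_start, la.ref_end)
        if key not in seen or la.matches > seen[key].matches:
            seen[key] = la
    return sorted(
        seen.values(),
        key=lambda a: (a.asm_id, a.ref_id, a.ref_start, a.asm_start, a.strand),
    )


def alignments_from_psl(
    rows: Sequence[PslAlignment],
    assembly: Assembly,
    reference: Sequence[SequenceRecord],
) -> list[LocalAlignment]:
    """Convert PSL rows (query = assembly, target = reference) to
    LocalAlignments, recomputing per-column identity from the sequences."""
    asm_by_id = {c.id: c for c in assembly}
    ref_by_id = {r.id: r for r in reference}
    out = []
    for row in rows:
        if row.qName not in asm_by_id:
            raise ValueError(f"PSL query {row.qName!r} not in assembly")
        if row.tName not in ref_by_id:
            raise ValueError(f"PSL target {row.tName!r} not in reference")
        contig = asm_by_id[row.qName]
        ref = ref_by_id[row.tName]
        strand = row.strand[0]
        qseq = contig.seq if strand == "+" else revcomp(contig.seq)
        matches = mismatches = 0
        q_hit: list[int] = []
        t_hit: list[int] = []
        for size, qs, ts in zip(row.blockSizes, row.qStarts, row.tStarts):
            for o in range(size):
                a, b = qseq[qs + o], ref.seq[ts + o]
                if a == b and a != "N":
                    matches += 1
                    q_hit.append(qs + o)
                    t_hit.append(ts + o)
                elif a != "N" and b != "N":
                    mismatches += 1
        if strand == "+":
            asm_pos = np.array(q_hit, dtype=np.int64)
        else:
            asm_pos = len(contig.seq) - 1 - np.array(q_hit, dtype=np.int64)
        out.append(
            LocalAlignment(
                asm_id=row.qName,
                ref_id=row.tName,
                strand=strand,
                asm_start=row.qStart,
                asm_end=row.qEnd,
                ref_start=row.tStart,
                ref_end=row.tEnd,
                matches=matches,
                mismatches=mismatches,
                indel_bases=row.qBaseInsert + row.tBaseInsert,
                asm_match_pos=asm_pos,
                ref_match_pos=np.array(t_hit, dtype=np.int64),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Contig-level measures
# ---------------------------------------------------------------------------

def contig_level_scores(
    alignments: Sequence[LocalAlignment],
    assembly: Assembly,
    reference: Sequence[SequenceRecord],
) -> tuple[float, float, float, list[tuple[str, str]]]:
    """Contig-level recall, precision, F1 and the matched pairs.

    An edge requires >= 99% of both sequences' non-N bases identical in a
    single alignment, with inserted+deleted bases <= 1% of the shorter non-N
    length; the counts come from the maximum-cardinality matching.
    """
    asm_ids = {c.id for c in assembly}
    ref_ids = {r.id for r in reference}
    for la in alignments:
        if la.asm_id not in asm_ids:
            raise ValueError(f"alignment references unknown assembly id {la.asm_id!r}")
        if la.ref_id not in ref_ids:
            raise ValueError(f"alignment references unknown reference id {la.ref_id!r}")
    asm_len = {c.id: _non_n_length(c.seq) for c in assembly}
    ref_len = {r.id: _non_n_length(r.seq) for r in reference}

    best: dict[tuple[str, str], LocalAlignment] = {}
    for la in alignments:
        key = (la.asm_id, la.ref_id)
        if key not in best or la.matches > best[key].matches:
            best[key] = la

    g = nx.Graph()
    a_nodes = [f"a::{c.id}" for c in assembly]
    g.add_nodes_from(a_nodes, bipartite=0)
    g.add_nodes_from([f"r::{r.id}" for r in reference], bipartite=1)
    for (aid, rid), la in best.items():
        la_len = min(asm_len[aid], ref_len[rid])
        if (
            la.matches >= 0.99 * asm_len[aid]
            and la.matches >= 0.99 * ref_len[rid]
            and la.indel_bases <= 0.01 * la_len
        ):
            g.add_edge(f"a::{aid}", f"r::{rid}")
    matching = nx.bipartite.maximum_matching(g, top_nodes=a_nodes)
    pairs = sorted(
        (a[3:], r[3:]) for a, r in matching.items() if a.startswith("a::")
    )
    recall = len(pairs) / len(ref_ids) if ref_ids else 0.0
    precision = len(pairs) / len(asm_ids) if asm_ids else 0.0
    return recall, precision, f1_score(recall, precision), pairs


# ---------------------------------------------------------------------------
# Nucleotide-level measures
# ---------------------------------------------------------------------------

def _greedy_cover(
    alignments: Sequence[LocalAlignment],
    universe_sizes: dict[str, int],
    side: str,
) -> int:
    """Greedy marginal-contribution selection; returns correct position count.

    Alignments are picked in order of how many still-unassigned positions
    they would recover correctly; a selected alignment then claims every
    position it spans (each position is assigned at most one alignment).
    Ties break toward the longer alignment, then lexicographic ids.
    """
    claimed = {sid: np.zeros(n, dtype=bool) for sid, n in universe_sizes.items()}
    remaining = list(alignments)
    total = 0
    while remaining:
        best_gain, best_idx, best_key = 0, None, None
        for i, la in enumerate(remaining):
            sid = la.ref_id if side == "ref" else la.asm_id
            pos = la.ref_match_pos if side == "ref" else la.asm_match_pos
            gain = int((~claimed[sid][pos]).sum()) if pos.size else 0
            key = (gain, la.aligned_len, la.asm_id, la.ref_id)
            if best_idx is None or (gain, la.aligned_len) > best_key[:2] or (
                (gain, la.aligned_len) == best_key[:2]
                and (la.asm_id, la.ref_id) < best_key[2:]
            ):
                best_key = key
                best_gain, best_idx = gain, i
        if best_gain <= 0:
            break
        la = remaining.pop(best_idx)
        if side == "ref":
            claimed[la.ref_id][la.ref_start : la.ref_end] = True
        else:
            claimed[la.asm_id][la.asm_start : la.asm_end] = True
        total += best_gain
    return total


def nucleotide_level_scores(
    alignments: Sequence[LocalAlignment],
    assembly: Assembly,
    reference: Sequence[SequenceRecord],
) -> tuple[float, float, float]:
    """Nucleotide-level recall, precision and F1.

    Denominators count non-N positions; a position is correct when the
    alignment greedily selected for it carries an identical base.
    """
    ref_sizes = {r.id: len(r.seq) for r in reference}
    asm_sizes = {c.id: len(c.seq) for c in assembly}
    ref_total = sum(_non_n_length(r.seq) for r in reference)
    asm_total = sum(_non_n_length(c.seq) for c in assembly)
    if not alignments or ref_total == 0 or asm_total == 0:
        return 0.0, 0.0, 0.0
    rec_hits = _greedy_cover(alignments, ref_sizes, side="ref")
    pre_hits = _greedy_cover(alignments, asm_sizes, side="asm")
    recall = rec_hits / ref_total
    precision = pre_hits / asm_total
    return recall, precision, f1_score(recall, precision)


def evaluate(
    assembly: Assembly,
    reference: Sequence[SequenceRecord],
    alignments: Optional[Sequence[LocalAlignment]] = None,
) -> EvalReport:
    """Contig- and nucleotide-level report, aligning internally if needed."""
    if alignments is None:
        alignments = align_assembly_to_reference(assembly, reference)
    c_rec, c_pre, c_f1, pairs = contig_level_scores(alignments, assembly, reference)
    n_rec, n_pre, n_f1 = nucleotide_level_scores(alignments, assembly, reference)
    return EvalReport(c_rec, c_pre, c_f1, n_rec, n_pre, n_f1, pairs)


# ---------------------------------------------------------------------------
# K-mer compression score
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _iter_kmers(seq: str, k: int, canonical: bool):
    """Yield packed k-mers (arbitrary k, Python ints); skips k-mers with N."""
    mask = (1 << (2 * k)) - 1
    shift_rc = 2 * (k - 1)
    fwd = rc = 0
    run = 0
    for ch in seq:
        code = _CODE.get(ch)
        if code is None:
            run = 0
            fwd = rc = 0
            continue
        fwd = ((fwd << 2) | code) & mask
        rc = (rc >> 2) | ((3 - code) << shift_rc)
        run += 1
        if run >= k:
            yield min(fwd, rc) if canonical else fwd


def kc_score(
    assembly: Assembly,
    reference: Sequence[SequenceRecord],
    tau: Sequence[float],
    n_reads: int,
    read_len: int,
    k: Optional[int] = None,
    strand_specific: bool = False,
) -> tuple[float, float, float]:
    """(KC, WKR, ICR) of an assembly against abundance-weighted references.

    WKR sums, over the distinct k-mers present in the assembly, the
    reference k-mer frequency p(r) = sum_b n(r,b) tau(b) / sum_b n(b) tau(b).
    ICR = |A| / (N L).  k defaults to the read length.  K-mers are counted
    strand-canonically unless the protocol is strand-specific.
    """
    if k is None:
        k = read_len
    if k < 1:
        raise ValueError("k must be >= 1")
    tau = np.asarray(tau, dtype=float)
    if tau.size != len(reference):
        raise ValueError("tau must have one entry per reference sequence")
    if abs(tau.sum() - 1.0) > 1e-6:
        raise ValueError("tau must sum to 1")
    if all(len(r.seq) < k for r in reference):
        raise ValueError(f"k={k} exceeds every reference sequence length")
    canonical = not strand_specific

    p: dict[int, float] = {}
    denom = 0.0
    for b, t in zip(reference, tau):
        if t == 0:
            continue
        for kmer in _iter_kmers(b.seq, k, canonical):
            p[kmer] = p.get(kmer, 0.0) + t
            denom += t
    if denom == 0:
        raise ValueError("no reference k-mers with positive abundance")

    asm_kmers: set[int] = set()
    for c in assembly:
        asm_kmers.update(_iter_kmers(c.seq, k, canonical))
    wkr = sum(p.get(r, 0.0) for r in asm_kmers) / denom
    icr = assembly.total_bases / (n_reads * read_len)
    return wkr - icr, wkr, icr


def estimate_abundances(
    reads: ReadSet,
    reference: Sequence[SequenceRecord],
    params: ModelParams,
    em_tol: float = 1e-4,
) -> np.ndarray:
    """Relative molar abundances tau of reference sequences from reads.

    Fits read fractions theta by EM and converts to molar fractions by
    dividing out effective lengths.
    """
    ref_assembly = Assembly(list(reference))
    est = em_fit(reads, ref_assembly, params, tol=em_tol)
    eff = np.maximum(
        np.asarray(ref_assembly.lengths, dtype=float) - params.L + 1, 1.0
    )
    tau = est.theta[1:] / eff
    total = tau.sum()
    if total <= 0:
        return np.full(len(reference), 1.0 / len(reference))
    return tau / total


# ---------------------------------------------------------------------------
# Size statistics
# ---------------------------------------------------------------------------

def n50(assembly: Assembly) -> int:
    """Longest length such that contigs at least that long cover half the bases."""
    if assembly.M == 0:
        raise ValueError("N50 of an empty assembly is undefined")
    lengths = np.sort(np.asarray(assembly.lengths))[::-1]
    half = lengths.sum() / 2.0
    csum = np.cumsum(lengths)
    return int(lengths[np.searchsorted(csum, half)])
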