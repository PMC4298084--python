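"""The true assembly of a read set, and its estimation from real reads.

Given the true origin of every read, the true assembly at minimum overlap
length w is the set of maximal transcript segments [start, end] for which an
ordered set of reads exists with: all reads from that transcript, the first
read's left end at `start`, the last read's right end at `end`, and every
consecutive pair overlapping by at least w bases (at w = 0, exact adjacency
also extends a contig).  It is the best assembly theoretically achievable by
an assembler that requires w bases of overlap to merge reads.

For real reads the true origins are unknown; :func:`estimate_true_assembly`
reproduces them by aligning reads to a reference transcript set, fitting
abundances by EM, and sampling one alignment per read from its posterior
(reads sampled to the noise component are dropped), then building the true
contigs at w = 0 from the sampled origins.

With paired-end origins, true contigs linked by a read pair are chained into
scaffolds: contigs are vertices, spanning pairs are edges, and each
connected component becomes one scaffold with uncovered gaps written as runs
of N whose lengths come from the contigs' positions on the parent transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .read_model import (
    AssemblyIndex,
    ModelParams,
    PreparedReads,
    _EmWorkspace,
    em_fit,
)
from .records import Assembly, Origin, Read, ReadSet, SequenceRecord


@dataclass
class TrueContig:
    """A maximal read-covered transcript segment (1-based inclusive bounds)."""

    transcript_id: str
    start: int
    end: int
    seq: str
    supporting_reads: list[str] = field(default_factory=list)
    # positions at which a read was merged into the growing segment:
    # (left of the incoming read, rightmost covered position before the merge)
    merge_points: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def true_contigs(
    reads: Sequence[Read],
    transcripts: Sequence[SequenceRecord],
    w: int = 0,
) -> list[TrueContig]:
    """True contigs at minimum overlap length w from origin-annotated reads.

    Reads are swept in order of their left ends per transcript; a read
    extends the open segment iff current_right - left + 1 >= w, i.e. it
    overlaps the segment's rightmost covered position by at least w bases
    (w = 0 admits exact adjacency).  Emitted segments are maximal.
    """
    if w < 0:
        raise ValueError("w must be a non-negative integer")
    by_id = {t.id: t for t in transcripts}
    per_transcript: dict[str, list[Read]] = {}
    for r in reads:
        if r.origin is None:
            raise ValueError(f"read {r.id!r} has no origin")
        if r.origin.transcript_id not in by_id:
            raise ValueError(
                f"read {r.id!r} references unknown transcript "
                f"{r.origin.transcript_id!r}"
            )
        per_transcript.setdefault(r.origin.transcript_id, []).append(r)

    out: list[TrueContig] = []
    for t in transcripts:
        group = per_transcript.get(t.id)
        if not group:
            continue
        group.sort(key=lambda r: (r.origin.left, r.origin.right, r.id))
        open_reads: list[Read] = []
        merge_points: list[tuple[int, int]] = []
        start = cur_right = None

        def close():
            out.append(
                TrueContig(
                    t.id,
                    start,
                    cur_right,
                    t.seq[start - 1 : cur_right],
                    [r.id for r in open_reads],
                    merge_points,
                )
            )

        for r in group:
            o = r.origin
            if start is None:
                start, cur_right = o.left, o.right
                open_reads = [r]
                merge_points = []
            elif cur_right - o.left + 1 >= w:
                merge_points.append((o.left, cur_right))
                open_reads.append(r)
                cur_right = max(cur_right, o.right)
            else:
                close()
                start, cur_right = o.left, o.right
                open_reads = [r]
                merge_points = []
        if start is not None:
            close()
    return out


def contigs_to_assembly(contigs: Sequence[TrueContig], prefix: str = "tc") -> Assembly:
    records = [
        SequenceRecord(f"{prefix}{i}_{c.transcript_id}:{c.start}-{c.end}", c.seq)
        for i, c in enumerate(contigs)
    ]
    return Assembly(records)


def true_scaffolds(
    contigs: Sequence[TrueContig],
    read_pairs: Sequence[tuple[Read, Read]],
) -> list[SequenceRecord]:
    """Join true contigs spanned by read pairs into scaffolds.

    Each connected component of the contig/pair graph becomes one scaffold;
    contigs are ordered by transcript coordinate and separated by runs of N
    sized by their gap on the parent transcript.  Without spanning pairs the
    scaffolds are the contigs themselves.
    """
    contigs = list(contigs)

    def locate(read: Read) -> Optional[int]:
        o = read.origin
        if o is None:
            return None
        for i, c in enumerate(contigs):
            if c.transcript_id == o.transcript_id and c.start <= o.left and o.right <= c.end:
                return i
        return None

    g = nx.Graph()
    g.add_nodes_from(range(len(contigs)))
    for r1, r2 in read_pairs:
        if r1.origin is None or r2.origin is None:
            continue
        if r1.origin.transcript_id != r2.origin.transcript_id:
            raise ValueError(
                f"mates {r1.id!r}/{r2.id!r} originate from different transcripts"
            )
        i, j = locate(r1), locate(r2)
        if i is not None and j is not None and i != j:
            g.add_edge(i, j)

    records: list[SequenceRecord] = []
    serial = 0
    for comp in sorted(nx.connected_components(g), key=min):
        members = sorted(comp, key=lambda i: (contigs[i].transcript_id, contigs[i].start))
        pieces = [contigs[members[0]].seq]
        prev = contigs[members[0]]
        for i in members[1:]:
            cur = contigs[i]
            gap = cur.start - prev.end - 1
            pieces.append("N" * max(gap, 0))
            pieces.append(cur.seq)
            prev = cur
        first = contigs[members[0]]
        records.append(
            SequenceRecord(
                f"sc{serial}_{first.transcript_id}:{first.start}-{prev.end}",
                "".join(pieces),
            )
        )
        serial += 1
    return records


def sample_posterior_origins(
    reads: ReadSet,
    transcripts: Sequence[SequenceRecord],
    params: ModelParams,
    seed: int,
    em_tol: float = 1e-4,
) -> list[Read]:
    """One sampled origin per read from its posterior alignment distribution.

    Reads sampled to the noise component are dropped.  Sampling is
    inverse-CDF over the deterministic alignment order, so results are
    reproducible given the seed.
    """
    reference = Assembly(list(transcripts))
    prep = PreparedReads(reads, params)
    index = AssemblyIndex(reference, params)
    ws = _EmWorkspace(prep, index, params)
    est = em_fit(reads, reference, params, tol=em_tol, workspace=ws)
    with np.errstate(divide="ignore"):
        logw = np.log(est.theta)[ws.comp] + ws.emit
    lse = ws.per_read_logsumexp(logw)
    post = np.exp(logw - lse[ws.read_idx])

    rng = np.random.default_rng(seed)
    u = rng.random(prep.n)
    cs = np.cumsum(post)
    base = cs[ws.seg_starts] - post[ws.seg_starts]
    within = cs - base[ws.read_idx]
    hit_rows = np.nonzero(within >= u[ws.read_idx] - 1e-12)[0]
    _, first_idx = np.unique(ws.read_idx[hit_rows], return_index=True)
    chosen = hit_rows[first_idx]

    # map workspace rows back to alignment coordinates: contig rows of the
    # workspace appear in the same order as the alignment arrays
    contig_row_pos = np.full(ws.read_idx.size, -1, dtype=np.int64)
    contig_row_pos[ws.comp > 0] = np.arange(int((ws.comp > 0).sum()))

    out: list[Read] = []
    L = params.L
    for row in chosen:
        comp = int(ws.comp[row])
        if comp == 0:
            continue
        ridx = int(ws.read_idx[row])
        arr_i = int(contig_row_pos[row])
        start = int(ws.arr["start"][arr_i])
        strand = "+" if ws.arr["strand"][arr_i] == 0 else "-"
        read = reads.reads[ridx]
        tid = transcripts[comp - 1].id
        out.append(
            Read(
                read.id,
                read.seq,
                origin=Origin(tid, start + 1, start + L, strand),
                mate=read.mate,
            )
        )
    return out


def estimate_true_assembly(
    reads: ReadSet,
    reference_transcripts: Sequence[SequenceRecord],
    params: ModelParams,
    seed: int,
    w: int = 0,
) -> Assembly:
    """Estimate the true assembly of a read set against reference transcripts.

    Aligns reads to the transcripts, fits abundances by EM, samples one
    alignment per read from the posterior (noise samples discard the read),
    treats the samples as true origins and builds the true contigs at the
    given minimum overlap length.  Paired read sets additionally chain
    contigs spanned by a surviving mate pair into scaffolds.
    """
    sampled = sample_posterior_origins(reads, reference_transcripts, params, seed)
    if not sampled:
        raise ValueError("no reads survived posterior sampling")
    contigs = true_contigs(sampled, reference_transcripts, w=w)
    if reads.paired:
        by_serial: dict[str, list[Read]] = {}
        for r in sampled:
            by_serial.setdefault(r.id.split("/")[0], []).append(r)
        pairs = [tuple(v) for v in by_serial.values() if len(v) == 2]
        pairs = [
            p for p in pairs
            if p[0].origin.transcript_id == p[1].origin.transcript_id
        ]
        return Assembly(true_scaffolds(contigs, pairs))
    return contigs_to_assembly(contigs)
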