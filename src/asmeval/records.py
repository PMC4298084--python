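"""Core domain types: sequences, reads with true origins, assemblies, PSL rows.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open.  The one exception is
``Origin.left``/``Origin.right``, which mirror the field convention for the
true placement of a read on its source transcript: 1-based, inclusive at both
ends.  :func:`to_zero_based` / :func:`to_one_based` convert between the two
and are inverses of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


def to_zero_based(left: int, right: int) -> tuple[int, int]:
    """1-based inclusive [left, right] -> 0-based half-open [start, end)."""
    return left - 1, right


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive [left, right]."""
    return start + 1, end


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Origin:
    """True placement of a read on its source transcript (1-based inclusive)."""

    transcript_id: str
    left: int
    right: int
    strand: str

    def __post_init__(self):
        if self.left < 1 or self.right < self.left:
            raise ValueError(f"invalid origin interval [{self.left}, {self.right}]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.right - self.left + 1


@dataclass(frozen=True)
class Read:
    """A sequenced read, optionally annotated with its true origin."""

    id: str
    seq: str
    origin: Optional[Origin] = None
    mate: Optional[int] = None

    def __post_init__(self):
        if self.origin is not None and self.origin.length != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: origin span {self.origin.length} != "
                f"read length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadSet:
    """A collection of same-length single-end reads (or read pairs)."""

    reads: list[Read]
    paired: bool = False

    def __post_init__(self):
        if not self.reads:
            raise ValueError("read set is empty")
        lengths = {len(r) for r in self.reads}
        if not self.paired and len(lengths) != 1:
            raise ValueError(f"single-end reads must share one length, got {sorted(lengths)}")

    @property
    def N(self) -> int:
        """Number of reads (read pairs when paired)."""
        if self.paired:
            return len(self.reads) // 2
        return len(self.reads)

    @property
    def L(self) -> int:
        return len(self.reads[0])

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class Assembly:
    """An ordered collection of contigs (or scaffolds)."""

    contigs: list[SequenceRecord]

    def __post_init__(self):
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("assembly contig ids must be unique")

    @property
    def M(self) -> int:
        return len(self.contigs)

    @property
    def lengths(self) -> list[int]:
        return [len(c) for c in self.contigs]

    @property
    def total_bases(self) -> int:
        return sum(len(c) for c in self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], prefix: str = "contig") -> "Assembly":
        return cls([SequenceRecord(f"{prefix}_{i}", s) for i, s in enumerate(seqs)])


PSL_COLUMNS = (
    "matches misMatches repMatches nCount qNumInsert qBaseInsert "
    "tNumInsert tBaseInsert strand qName qSize qStart qEnd "
    "tName tSize tStart tEnd blockCount blockSizes qStarts tStarts"
).split()


@dataclass(frozen=True)
class PslAlignment:
    """One row of a 21-column PSL local-alignment file (0-based half-open)."""

    matches: int
    misMatches: int
    repMatches: int
    nCount: int
    qNumInsert: int
    qBaseInsert: int
    tNumInsert: int
    tBaseInsert: int
    strand: str
    qName: str
    qSize: int
    qStart: int
    qEnd: int
    tName: str
    tSize: int
    tStart: int
    tEnd: int
    blockCount: int
    blockSizes: tuple[int, ...] = field(default_factory=tuple)
    qStarts: tuple[int, ...] = field(default_factory=tuple)
    tStarts: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not (0 <= self.qStart < self.qEnd <= self.qSize):
            raise ValueError(f"PSL query interval invalid for {self.qName}")
        if not (0 <= self.tStart < self.tEnd <= self.tSize):
            raise ValueError(f"PSL target interval invalid for {self.tName}")
        for name in ("blockSizes", "qStarts", "tStarts"):
            if len(getattr(self, name)) != self.blockCount:
                raise ValueError(f"PSL {name} has wrong number of entries")
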