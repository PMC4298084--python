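"""FASTA/FASTQ/PSL I/O and the read-name encoding of true read origins.

FASTA and FASTQ parsing is delegated to Biopython's SeqIO; this module adds
the validation the rest of the package relies on (unique non-empty ids,
non-empty sequences, uppercasing, U->T) and transparent gzip support.
FASTQ quality strings are parsed and discarded: the read model has no
quality term.
"""

from __future__ import annotations

import gzip
import io
import re
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .records import Origin, PslAlignment, Read, ReadSet, SequenceRecord

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


class FormatError(ValueError):
    """Raised for malformed sequence or alignment files."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_seq(raw: str, where: str) -> str:
    seq = str(raw).upper().replace("U", "T")
    if not seq:
        raise FormatError(f"empty sequence for record {where}")
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise FormatError(f"record {where} contains invalid characters {bad}")
    return seq


def _check_id(name: str, seen: set, where: str) -> None:
    if not name:
        raise FormatError(f"missing id at {where}")
    if any(ch.isspace() for ch in name):
        raise FormatError(f"id {name!r} contains whitespace")
    if name in seen:
        raise FormatError(f"duplicate id {name!r}")
    seen.add(name)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into validated records."""
    records = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        text = fh.read()
    # Biopython silently yields empty sequences for headers with no body;
    # locate them ourselves so the error can name the offending record.
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.startswith(">") and not line[1:].strip():
            raise FormatError(f"{path}: header with no id at line {lineno}")
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        _check_id(rec.id, seen, f"{path}")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(SequenceRecord(rec.id, _clean_seq(rec.seq, rec.id)))
    if not records and text.strip():
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    """Write records as FASTA; round-trips with :func:`read_fasta`."""
    records = list(records)
    seen: set[str] = set()
    for rec in records:
        _check_id(rec.id, seen, "output")
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path, paired: bool = False) -> ReadSet:
    """Read a (possibly gzipped) FASTQ file; qualities are discarded.

    Origins encoded in read names (see :func:`encode_origin`) are decoded
    automatically; other names yield reads without origins.
    """
    reads = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            _check_id(rec.id, seen, f"{path}")
            seq = _clean_seq(rec.seq, rec.id)
            reads.append(Read(rec.id, seq, origin=decode_origin(rec.id, length=len(seq))))
    if not reads:
        raise FormatError(f"{path}: no FASTQ records found")
    return ReadSet(reads, paired=paired)


def write_fastq(readset: ReadSet, path) -> None:
    """Write reads as FASTQ with constant placeholder qualities."""
    with _open_text(path, "wt") as fh:
        for read in readset:
            fh.write(f"@{read.id}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")


# ---------------------------------------------------------------------------
# Read-name origin encoding: {serial}_{transcript_id}_{left}_{right}_{strand}
# ---------------------------------------------------------------------------

def encode_origin(serial: int, origin: Origin) -> str:
    """Encode a true origin into a read name."""
    return f"{serial}_{origin.transcript_id}_{origin.left}_{origin.right}_{origin.strand}"


def decode_origin(name: str, length: Optional[int] = None) -> Optional[Origin]:
    """Decode an origin from a read name; non-conforming names yield None.

    Transcript ids may themselves contain underscores: the serial is the
    first field and left/right/strand the last three.
    """
    parts = name.split("_")
    if len(parts) < 5:
        return None
    serial, left_s, right_s, strand = parts[0], parts[-3], parts[-2], parts[-1]
    tid = "_".join(parts[1:-3])
    if not (serial.isdigit() and left_s.isdigit() and right_s.isdigit()):
        return None
    if strand not in ("+", "-") or not tid:
        return None
    origin = Origin(tid, int(left_s), int(right_s), strand)
    if length is not None and origin.length != length:
        raise FormatError(
            f"read name {name!r}: origin span {origin.length} != read length {length}"
        )
    return origin


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------

def _int_list(fieldval: str) -> tuple[int, ...]:
    return tuple(int(x) for x in fieldval.rstrip(",").split(",") if x)


def read_psl(path) -> list[PslAlignment]:
    """Read a 21-column BLAT PSL file (5-line header optional).

    Coordinates are kept 0-based half-open as in the PSL format.
    """
    rows = []
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        start = 5  # fixed-size header block
    for lineno in range(start, len(lines)):
        line = lines[lineno].rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) != 21:
            raise FormatError(
                f"{path}: line {lineno + 1}: expected 21 PSL columns, got {len(fields)}"
            )
        try:
            row = PslAlignment(
                matches=int(fields[0]),
                misMatches=int(fields[1]),
                repMatches=int(fields[2]),
                nCount=int(fields[3]),
                qNumInsert=int(fields[4]),
                qBaseInsert=int(fields[5]),
                tNumInsert=int(fields[6]),
                tBaseInsert=int(fields[7]),
                strand=fields[8],
                qName=fields[9],
                qSize=int(fields[10]),
                qStart=int(fields[11]),
                qEnd=int(fields[12]),
                tName=fields[13],
                tSize=int(fields[14]),
                tStart=int(fields[15]),
                tEnd=int(fields[16]),
                blockCount=int(fields[17]),
                blockSizes=_int_list(fields[18]),
                qStarts=_int_list(fields[19]),
                tStarts=_int_list(fields[20]),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno + 1}: {exc}") from exc
        rows.append(row)
    return rows


def write_psl(rows: Iterable[PslAlignment], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.matches, r.misMatches, r.repMatches, r.nCount,
                        r.qNumInsert, r.qBaseInsert, r.tNumInsert, r.tBaseInsert,
                        r.strand, r.qName, r.qSize, r.qStart, r.qEnd,
                        r.tName, r.tSize, r.tStart, r.tEnd, r.blockCount,
                        ",".join(map(str, r.blockSizes)) + ",",
                        ",".join(map(str, r.qStarts)) + ",",
                        ",".join(map(str, r.tStarts)) + ",",
                    )
                )
                + "\n"
            )
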