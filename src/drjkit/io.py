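"""Sequence and interval I/O.

Coordinate convention: every interval in this package is 0-based, half-open,
on the forward strand.  BED files are read and written natively in that
convention; a 1-based inclusive TSV dialect can be converted at parse time
via ``one_based=True``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

_VALID = set("ACGTN")


class FastaFormatError(ValueError):
    """Malformed FASTA/FASTQ input; message carries the offending line."""


class LocusValidationError(ValueError):
    """Locus table entry inconsistent with itself or with the genome."""


@dataclass(frozen=True)
class Scaffold:
    """A reference sequence (genome scaffold)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise FastaFormatError("scaffold with empty id")
        if not self.sequence:
            raise FastaFormatError(f"scaffold {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CircleRead:
    """One sequencing read of a circularized viral molecule."""

    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProviralLocus:
    """An integrated proviral segment locus on a scaffold."""

    name: str
    scaffold_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise LocusValidationError(
                f"locus {self.name!r}: invalid interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _check_alphabet(seq: str, record_id: str, line_no: int) -> None:
    bad = set(seq) - _VALID
    if bad:
        raise FastaFormatError(
            f"line {line_no}: record {record_id!r} contains invalid "
            f"characters {sorted(bad)}"
        )


def read_fasta(path, as_reads: bool = False):
    """Read a FASTA file into Scaffold (default) or CircleRead records.

    Sequences are upper-cased; characters outside {A,C,G,T,N} are rejected
    with an error naming the line.  Order of records is preserved.
    """
    records = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no):
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FastaFormatError(
                f"line {header_line}: record {header!r} has no sequence"
            )
        _check_alphabet(seq, header, line_no)
        if header in seen:
            raise FastaFormatError(
                f"line {header_line}: duplicate record id {header!r}"
            )
        seen.add(header)
        cls = CircleRead if as_reads else Scaffold
        records.append(cls(id=header, sequence=seq))
        header, chunks = None, []

    with open(path) as fh:
        n = 0
        for n, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(n - 1)
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaFormatError(f"line {n}: empty FASTA header")
                header_line = n
            elif header is None:
                raise FastaFormatError(f"line {n}: sequence before any header")
            else:
                chunks.append(line)
        flush(n)
    return records


def read_fastq(path) -> list[CircleRead]:
    """Read FASTQ reads (qualities kept as Phred scores)."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        _check_alphabet(seq, rec.id, 0)
        quals = tuple(rec.letter_annotations["phred_quality"])
        reads.append(CircleRead(id=rec.id, sequence=seq, qualities=quals))
    return reads


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_locus_table(
    path,
    scaffolds: Sequence[Scaffold] | None = None,
    one_based: bool = False,
) -> list[ProviralLocus]:
    """Read a BED3+name (or 4-column TSV) locus table.

    ``one_based=True`` converts a 1-based inclusive dialect to the internal
    0-based half-open convention at parse time.
    """
    by_id = {s.id: s for s in scaffolds} if scaffolds is not None else None
    loci: list[ProviralLocus] = []
    names: set[str] = set()
    with open(path) as fh:
        for n, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise LocusValidationError(
                    f"line {n}: expected 4 columns (scaffold, start, end, name)"
                )
            scaffold_id, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise LocusValidationError(f"line {n}: non-integer coordinate") from exc
            if one_based:
                start -= 1
            if start >= end:
                raise LocusValidationError(
                    f"line {n}: locus {name!r} has start >= end"
                )
            if name in names:
                raise LocusValidationError(f"line {n}: duplicate locus name {name!r}")
            names.add(name)
            if by_id is not None:
                if scaffold_id not in by_id:
                    raise LocusValidationError(
                        f"line {n}: unknown scaffold {scaffold_id!r}"
                    )
                if end > len(by_id[scaffold_id]):
                    raise LocusValidationError(
                        f"line {n}: locus {name!r} extends past scaffold end"
                    )
            loci.append(ProviralLocus(name=name, scaffold_id=scaffold_id,
                                      start=start, end=end))
    return loci


@dataclass(frozen=True)
class BedRecord:
    scaffold_id: str
    start: int
    end: int
    name: str = "."
    score: float | None = None


def write_bed(records: Iterable, path) -> None:
    """Write intervals as BED (0-based half-open).

    Accepts BedRecord, ProviralLocus, or any object exposing
    scaffold_id/start/end and optionally name/score.
    """
    with open(path, "w") as fh:
        fh.write("#scaffold\tstart\tend\tname\tscore\n")
        for rec in records:
            name = getattr(rec, "name", ".") or "."
            score = getattr(rec, "score", None)
            score_s = "." if score is None else f"{score:g}"
            fh.write(
                f"{rec.scaffold_id}\t{rec.start}\t{rec.end}\t{name}\t{score_s}\n"
            )


def read_bed(path) -> list[BedRecord]:
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            score = None if len(f) < 5 or f[4] == "." else float(f[4])
            out.append(BedRecord(f[0], int(f[1]), int(f[2]),
                                 f[3] if len(f) > 3 else ".", score))
    return out
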