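"""FASTA/BED input-output and interval arithmetic.

Every coordinate in this package is 0-based, half-open (the BED convention):
an interval ``(chrom, start, end)`` covers bases ``start .. end-1`` and has
length ``end - start``.  Soft-masked (lowercase) bases are uppercased; IUPAC
ambiguity codes other than N are mapped to N with a warning, because the
one-hot alphabet downstream knows exactly five symbols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from intervaltree import IntervalTree

ALPHABET = frozenset("ACGTN")
_IUPAC_EXTRA = frozenset("RYSWKMBDHVU")


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the format."""


class BedFormatError(ValueError):
    """Raised when a BED line cannot be parsed or violates invariants."""


@dataclass
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomicInterval:
    """A 0-based half-open chromosomal span with optional score and strand."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    strand: str | None = None
    name: str | None = field(default=None)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def _normalize_seq(raw: str, line_no: int) -> str:
    """Uppercase, map non-N ambiguity codes to N, reject anything else."""
    seq = raw.upper()
    bad = set(seq) - ALPHABET
    if not bad:
        return seq
    mappable = bad & _IUPAC_EXTRA
    illegal = bad - _IUPAC_EXTRA
    if illegal:
        sym = sorted(illegal)[0]
        raise FastaFormatError(
            f"illegal character {sym!r} in sequence at line {line_no}"
        )
    warnings.warn(
        f"line {line_no}: IUPAC ambiguity codes {sorted(mappable)} mapped to N",
        stacklevel=3,
    )
    table = str.maketrans({c: "N" for c in mappable})
    return seq.translate(table)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record, possibly line-wrapped) FASTA file.

    Sequences are normalized to uppercase {A,C,G,T,N}; record order is
    preserved.  An empty file yields an empty list.
    """
    records: list[SequenceRecord] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaFormatError(f"record {current_id!r} has an empty sequence")
        records.append(SequenceRecord(current_id, seq))

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].strip() else ""
                if not current_id:
                    raise FastaFormatError(f"empty FASTA header at line {line_no}")
                chunks = []
            else:
                if current_id is None:
                    raise FastaFormatError(
                        f"sequence data before first header at line {line_no}"
                    )
                chunks.append(_normalize_seq(line, line_no))
        flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records in FASTA format with lines wrapped at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ (tab-separated, no header); columns beyond 6 are ignored."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"line {line_no}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"line {line_no}: non-integer coordinate in {fields[1:3]}"
                ) from exc
            if start >= end or start < 0:
                raise BedFormatError(
                    f"line {line_no}: invalid coordinates start={start} end={end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedFormatError(
                        f"line {line_no}: non-numeric score {fields[4]!r}"
                    ) from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            intervals.append(GenomicInterval(chrom, start, end, score, strand, name))
    return intervals


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return f"{score:.6f}"


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, columns: int = 6) -> None:
    """Write intervals as BED3 or BED6 (name/score '.' when absent)."""
    if columns not in (3, 6):
        raise ValueError("columns must be 3 or 6")
    with open(path, "w") as fh:
        for iv in intervals:
            if columns == 3:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{_fmt_score(iv.score)}\t{iv.strand or '.'}\n"
                )


def extract_sequence(genome: list[SequenceRecord] | dict[str, str], iv: GenomicInterval) -> str:
    """Return the forward-strand genome substring covered by ``iv``."""
    if isinstance(genome, dict):
        seqs = genome
    else:
        seqs = {rec.id: rec.seq for rec in genome}
    if iv.chrom not in seqs:
        raise KeyError(f"chromosome {iv.chrom!r} not in genome")
    seq = seqs[iv.chrom]
    if iv.end > len(seq):
        raise IndexError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
            f"length {len(seq)}"
        )
    return seq[iv.start : iv.end]


def intersect(
    a: list[GenomicInterval],
    b: list[GenomicInterval],
    min_overlap: int = 1,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All pairs (x in a, y in b) sharing >= ``min_overlap`` bp on one chromosome.

    Each pair is reported once, in order of ``a`` then overlap position.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for x in a:
        tree = trees.get(x.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(x.start, x.end), key=lambda h: h.data)
        for hit in hits:
            overlap = min(x.end, hit.end) - max(x.start, hit.begin)
            if overlap >= min_overlap:
                pairs.append((x, b[hit.data]))
    return pairs
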