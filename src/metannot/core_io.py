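"""Sequence records, coordinate primitives, codon tables and FASTA I/O.

Conventions used throughout the package:

* All in-memory coordinates are 0-based, half-open, on the forward strand.
  Files emitted for humans (ORF tables, annotation summaries) convert to
  1-based inclusive coordinates at the point of writing.
* Sequence case is significant and preserved: lowercase runs mark
  soft-masked regions (non-coding RNA space excluded from gene calling).
* Translation is case-insensitive, so soft-masking never changes a codon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data import CodonTable as _ncbi

__all__ = [
    "FastaParseError",
    "ValidationError",
    "Interval",
    "merge_intervals",
    "intersection_length",
    "SeqRecord",
    "ClearRange",
    "CodonTable",
    "MaskedSequence",
    "read_fasta",
    "write_fasta",
    "parse_clear_range",
    "apply_clear_range",
    "soft_mask",
    "masked_intervals",
    "revcomp",
    "translate",
]


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class ValidationError(ValueError):
    """Raised when a sequence violates its declared alphabet."""


# IUPAC alphabets.  'X' and '*' are legal in peptides ('*' only as a stop,
# which the structural component strips before emission but parsers accept).
_NUC_CHARS = frozenset("ACGTURYSWKMBDHVN")
_AA_CHARS = frozenset("ABCDEFGHIKLMNPQRSTVWXYZJUO*")

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on the forward strand."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def intersection(self, other: "Interval") -> int:
        """Length of the overlap with ``other`` (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Normalized union: sorted, disjoint, adjacent runs merged."""
    out: list[Interval] = []
    for iv in sorted(intervals):
        if out and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def intersection_length(iv: Interval, others: Sequence[Interval]) -> int:
    """Total overlap of ``iv`` with a *disjoint* interval list."""
    return sum(iv.intersection(o) for o in others)


@dataclass
class SeqRecord:
    """A FASTA record.

    ``offset`` records where ``seq`` starts on the original, full-length
    sequence (non-zero after clear-range extraction) so that downstream
    coordinates remain recoverable.
    """

    id: str
    seq: str
    description: str = ""
    offset: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")

    def validate(self, kind: str) -> "SeqRecord":
        alphabet = _NUC_CHARS if kind == "nucleotide" else _AA_CHARS
        bad = set(self.seq.upper()) - alphabet
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal {kind} characters {sorted(bad)}"
            )
        return self


@dataclass(frozen=True)
class ClearRange:
    """High-quality region of a read, as an internal-convention Interval."""

    interval: Interval


@dataclass(frozen=True)
class CodonTable:
    """An NCBI translation table.

    ``forward`` maps the 64 unambiguous codons to amino acids; stop codons
    are not in ``forward`` but in ``stops``.
    """

    table_id: int
    forward: dict[str, str]
    stops: frozenset[str]
    starts: frozenset[str]

    @classmethod
    def from_ncbi(cls, table_id: int = 11) -> "CodonTable":
        try:
            t = _ncbi.unambiguous_dna_by_id[table_id]
        except KeyError:
            raise ValueError(f"unknown NCBI translation table {table_id}") from None
        return cls(
            table_id=table_id,
            forward=dict(t.forward_table),
            stops=frozenset(t.stop_codons),
            starts=frozenset(t.start_codons),
        )

    def codon(self, c: str) -> str:
        """Translate one codon; ambiguity -> 'X', stop -> '*'."""
        c = c.upper()
        if c in self.stops:
            return "*"
        return self.forward.get(c, "X")


@dataclass
class MaskedSequence:
    """A nucleotide record whose lowercase runs are soft-masked regions."""

    record: SeqRecord
    masked: list[Interval] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA I/O — a deliberately small reader so parse errors can carry line
# numbers, which matters for multi-million-read inputs.


def read_fasta(path: str | Path, kind: str = "nucleotide") -> list[SeqRecord]:
    """Read a multi-FASTA file, preserving record order and letter case.

    Parameters
    ----------
    path : file path
    kind : ``"nucleotide"`` or ``"peptide"`` — selects the IUPAC alphabet
        used for validation.
    """
    if kind not in ("nucleotide", "peptide"):
        raise ValueError(f"kind must be nucleotide or peptide, got {kind!r}")
    records: list[SeqRecord] = []
    header_line = 0
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"line {header_line}: record with empty sequence")
        tok = header.split(None, 1)
        rec = SeqRecord(id=tok[0], seq=seq, description=tok[1] if len(tok) > 1 else "")
        records.append(rec.validate(kind))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
            else:
                if header is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.strip())
        flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA with fixed line wrapping (case preserved)."""
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Clear ranges

_CLEAR_RANGE_RE = re.compile(r"/clear_range=(\S+)")


def parse_clear_range(description: str, token: str = "clear_range") -> ClearRange | None:
    """Extract a ``/clear_range=<a>-<b>`` token (1-based inclusive) from a
    FASTA description, returning the internal 0-based half-open interval.

    Returns None when the token is absent; malformed tokens raise.
    """
    m = re.search(rf"/{re.escape(token)}=(\S+)", description)
    if m is None:
        return None
    payload = m.group(1)
    parts = payload.split("-")
    if len(parts) != 2 or not all(p.isdigit() for p in parts):
        raise FastaParseError(f"malformed clear-range token {payload!r}")
    a, b = int(parts[0]), int(parts[1])
    if a < 1 or a > b:
        raise FastaParseError(f"invalid clear range {a}-{b}")
    return ClearRange(Interval(a - 1, b))


def apply_clear_range(record: SeqRecord, cr: ClearRange) -> SeqRecord:
    """Restrict a record to its clear range.

    The returned record's ``offset`` is the clear-range start, so original
    coordinates are ``offset + local``.
    """
    iv = cr.interval
    if iv.end > len(record.seq):
        raise ValueError(
            f"clear range [{iv.start},{iv.end}) exceeds record {record.id} "
            f"length {len(record.seq)}"
        )
    return replace(record, seq=record.seq[iv.start : iv.end], offset=record.offset + iv.start)


# ---------------------------------------------------------------------------
# Soft-masking


def soft_mask(record: SeqRecord, regions: Iterable[Interval]) -> MaskedSequence:
    """Lowercase exactly the union of ``regions``; uppercase everywhere else.

    Length and letters are unchanged — masking carries information downstream
    without losing sequence.
    """
    merged = merge_intervals(regions)
    if merged and merged[-1].end > len(record.seq):
        raise ValueError(f"mask region exceeds record {record.id} bounds")
    seq = record.seq.upper()
    parts: list[str] = []
    pos = 0
    for iv in merged:
        parts.append(seq[pos : iv.start])
        parts.append(seq[iv.start : iv.end].lower())
        pos = iv.end
    parts.append(seq[pos:])
    masked_rec = replace(record, seq="".join(parts))
    return MaskedSequence(record=masked_rec, masked=merged)


def masked_intervals(seq: str) -> list[Interval]:
    """Recover the soft-masked (lowercase) runs of a sequence."""
    return [Interval(m.start(), m.end()) for m in re.finditer(r"[a-z]+", seq)]


# ---------------------------------------------------------------------------
# Translation


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware, case-preserving."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, table: CodonTable, frame: int) -> str:
    """Translate one reading frame.

    ``frame`` is +1..+3 (forward) or -1..-3 (reverse complement).  Codons
    containing any non-ACGT character translate to 'X' — never to a stop, so
    ambiguity runs cannot split an open reading frame.  The trailing partial
    codon is dropped.  Case is ignored.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"frame must be in +-1..3, got {frame}")
    if frame < 0:
        seq = revcomp(seq)
        frame = -frame
    s = seq.upper()[frame - 1 :]
    return "".join(table.codon(s[i : i + 3]) for i in range(0, len(s) - len(s) % 3, 3))
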