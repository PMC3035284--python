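"""Structural annotation: ncRNA masking and fragment-aware ORF extraction.

The gene-calling strategy is built for shotgun fragments, where most coding
regions are truncated by read boundaries:

1. Non-coding RNAs (tRNA hits and two stages of rRNA BLAST hits) are
   soft-masked and written to their own FASTA files.
2. A naive 6-frame scan emits every maximal stop-free codon run of at least
   ``min_orf_nt`` nucleotides.  Read edges act as virtual stop/start sites,
   so fragments of genes cut by the read boundary are kept and flagged as
   truncated.  No start codon is required by default: demanding ATG would
   discard every 5'-truncated fragment.
3. Ab-initio gene predictions "tag" the ORFs they overlap; tagged ORFs are
   the most probable proteins even where they extend past the prediction.

Overlap with soft-masked (ncRNA) space is tolerated only up to
``max_masked_overlap_nt``; an ORF must additionally keep at least
``min_unmasked_nt`` unmasked nucleotides (150 of the 180-nt minimum at the
defaults).

ORF spans cover the stop-free coding run only — the terminal stop codon is
not part of the span, so the minimum-length filter applies to coding
sequence.  Edge-truncated runs extend to the sequence boundary, including a
trailing partial codon on the 3' side (the partial codon is never
translated).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from .core_io import (
    CodonTable,
    Interval,
    MaskedSequence,
    SeqRecord,
    intersection_length,
    merge_intervals,
    revcomp,
    soft_mask,
    translate,
)
from .evidence import BlastHit

__all__ = [
    "NcrnaHit",
    "StructuralConfig",
    "OrfCall",
    "GenePrediction",
    "parse_trnascan",
    "rrna_hits_from_blast",
    "mask_ncrnas",
    "find_orfs",
    "parse_gene_calls",
    "write_gene_calls",
    "tag_orfs",
    "emit_peptides",
    "write_orf_table",
    "RRNA_STAGE_EVALUE",
]

Strand = Literal["+", "-"]

#: E-value ceilings for the two increasingly stringent rRNA BLAST stages.
RRNA_STAGE_EVALUE = {1: 0.1, 2: 1e-4}


@dataclass(frozen=True)
class NcrnaHit:
    """A non-coding RNA locus detected on an input sequence."""

    seq_id: str
    interval: Interval
    strand: Strand
    kind: Literal["tRNA", "rRNA"]
    source: str
    score: float


@dataclass
class StructuralConfig:
    """Tunable thresholds for ORF extraction.

    Defaults reflect that ~20% of a typical ~900 bp bacterial gene is the
    minimum worth annotating, and that up to 30 nt of the 180-nt minimum may
    fall in masked ncRNA space (150 unmasked nucleotides required).
    """

    min_orf_nt: int = 180
    max_masked_overlap_nt: int = 30
    min_unmasked_nt: int = 150
    codon_table: CodonTable = field(default_factory=CodonTable.from_ncbi)
    clear_range_mode: bool = False
    require_start_codon: bool = False


@dataclass
class OrfCall:
    """One candidate protein-coding region.

    ``interval`` is the stop-free coding span in forward-strand coordinates
    (terminal stop codon excluded).  ``frame`` is 1..3 on the ORF's own
    strand.  Truncation flags mark spans that abut a sequence edge in
    reading orientation.
    """

    seq_id: str
    interval: Interval
    strand: Strand
    frame: int
    truncated_5p: bool
    truncated_3p: bool
    masked_nt: int
    peptide: str
    tagged: bool = False
    tag_source: str | None = None

    @property
    def orf_id(self) -> str:
        return (
            f"{self.seq_id}_{self.interval.start + 1}_{self.interval.end}"
            f"_{self.strand}{self.frame}"
        )


@dataclass(frozen=True)
class GenePrediction:
    """An ab-initio gene call used to tag naive ORFs."""

    seq_id: str
    interval: Interval
    strand: Strand
    score: float
    predictor: str

    @property
    def pred_id(self) -> str:
        return (
            f"{self.predictor}|{self.seq_id}|"
            f"{self.interval.start + 1}-{self.interval.end}|{self.strand}"
        )


# ---------------------------------------------------------------------------
# ncRNA evidence parsing


def parse_trnascan(path: str | Path) -> list[NcrnaHit]:
    """Parse tRNAscan-SE tabular output.

    Columns: name, tRNA#, begin, end, isotype, anticodon, intron begin/end,
    score (1-based inclusive coordinates; begin > end encodes the minus
    strand).  Header/comment lines starting with letters followed by dashes
    or whitespace-only lines are skipped.
    """
    hits: list[NcrnaHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("Sequence", "Name", "----")):
                continue
            cols = line.split()
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected >=9 columns, got {len(cols)}")
            try:
                begin, end = int(cols[2]), int(cols[3])
                score = float(cols[8])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row: {exc}") from None
            strand: Strand = "+" if begin <= end else "-"
            lo, hi = sorted((begin, end))
            hits.append(
                NcrnaHit(
                    seq_id=cols[0],
                    interval=Interval(lo - 1, hi),
                    strand=strand,
                    kind="tRNA",
                    source="trnascan",
                    score=score,
                )
            )
    return hits


def rrna_hits_from_blast(hits: Iterable[BlastHit], stage: int) -> list[NcrnaHit]:
    """Convert nucleotide BLAST hits against an rRNA reference into rRNA
    loci, applying the stage-specific E-value ceiling (stage 1: 0.1,
    stage 2: 1e-4).

    The query-side aligned interval becomes the masked region; subject-side
    orientation (s_start > s_end) encodes the minus strand.
    """
    if stage not in RRNA_STAGE_EVALUE:
        raise ValueError(f"rRNA BLAST stage must be 1 or 2, got {stage}")
    ceiling = RRNA_STAGE_EVALUE[stage]
    out: list[NcrnaHit] = []
    for h in hits:
        if h.evalue > ceiling:
            continue
        strand: Strand = "+" if h.s_start <= h.s_end else "-"
        out.append(
            NcrnaHit(
                seq_id=h.query_id,
                interval=Interval(h.q_start - 1, h.q_end),
                strand=strand,
                kind="rRNA",
                source=f"blast_stage{stage}",
                score=h.bitscore,
            )
        )
    return out


def mask_ncrnas(
    record: SeqRecord, hits: Iterable[NcrnaHit]
) -> tuple[MaskedSequence, list[SeqRecord]]:
    """Soft-mask every ncRNA hit on ``record`` and emit one FASTA record per
    hit (reverse-complemented for minus-strand loci).

    Hits from all sources are unioned into a single mask.
    """
    hits = list(hits)
    counters: dict[str, int] = {}
    ncrna_records: list[SeqRecord] = []
    for h in hits:
        if h.seq_id != record.id:
            raise ValueError(f"hit on {h.seq_id!r} applied to record {record.id!r}")
        n = counters.get(h.kind, 0) + 1
        counters[h.kind] = n
        sub = record.seq[h.interval.start : h.interval.end].upper()
        if h.strand == "-":
            sub = revcomp(sub)
        ncrna_records.append(
            SeqRecord(
                id=f"{record.id}.{h.kind}.{n}",
                seq=sub,
                description=(
                    f"/source={h.source} /coords={h.interval.start + 1}-{h.interval.end}"
                    f" /strand={h.strand}"
                ),
            )
        )
    ms = soft_mask(record, [h.interval for h in hits])
    return ms, ncrna_records


# ---------------------------------------------------------------------------
# ORF extraction


def find_orfs(ms: MaskedSequence, cfg: StructuralConfig | None = None) -> list[OrfCall]:
    """Naive 6-frame ORF scan with fragment semantics.

    For each strand and frame, every maximal stop-free codon run becomes a
    candidate; sequence edges act as virtual stops, and such edge-abutting
    candidates are flagged truncated.  A candidate is retained when its
    coding span is at least ``min_orf_nt``, overlaps soft-masked space by at
    most ``max_masked_overlap_nt``, and keeps at least ``min_unmasked_nt``
    unmasked positions.  Masking never alters translation.
    """
    cfg = cfg or StructuralConfig()
    rec = ms.record
    L = len(rec.seq)
    masked = merge_intervals(ms.masked)
    table = cfg.codon_table
    calls: list[OrfCall] = []
    for strand in ("+", "-"):
        oriented = rec.seq if strand == "+" else revcomp(rec.seq)
        upper = oriented.upper()
        for frame in (1, 2, 3):
            off = frame - 1
            n_codons = (L - off) // 3
            stop_idx = [
                i
                for i in range(n_codons)
                if upper[off + 3 * i : off + 3 * i + 3] in table.stops
            ]
            # runs between consecutive stops; -1 / None are the virtual edges
            bounds = [-1] + stop_idx + [None]
            for prev, nxt in zip(bounds[:-1], bounds[1:]):
                start_local = off + 3 * (prev + 1)
                if nxt is None:
                    end_local = L  # run off the 3' edge, partial codon included
                    trunc3 = True
                else:
                    end_local = off + 3 * nxt
                    trunc3 = False
                span = end_local - start_local
                if span < cfg.min_orf_nt:
                    continue
                trunc5 = prev == -1
                if cfg.require_start_codon and not trunc5:
                    if upper[start_local : start_local + 3] not in table.starts:
                        continue
                if strand == "+":
                    iv = Interval(start_local, end_local)
                else:
                    iv = Interval(L - end_local, L - start_local)
                masked_nt = intersection_length(iv, masked)
                if masked_nt > cfg.max_masked_overlap_nt:
                    continue
                if span - masked_nt < cfg.min_unmasked_nt:
                    continue
                peptide = translate(oriented[start_local:end_local], table, 1)
                calls.append(
                    OrfCall(
                        seq_id=rec.id,
                        interval=iv,
                        strand=strand,
                        frame=frame,
                        truncated_5p=trunc5,
                        truncated_3p=trunc3,
                        masked_nt=masked_nt,
                        peptide=peptide,
                    )
                )
    calls.sort(key=lambda c: (c.interval.start, c.interval.end, c.strand, c.frame))
    return calls


# ---------------------------------------------------------------------------
# Gene-call tagging

_GENE_CALL_COLS = ["seq_id", "start", "end", "strand", "score", "predictor"]


def parse_gene_calls(path: str | Path) -> list[GenePrediction]:
    """Read the canonical gene-call TSV (seq_id, start, end, strand, score,
    predictor; 1-based inclusive, strand explicit)."""
    preds: list[GenePrediction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
            seq_id, start_s, end_s, strand, score_s, predictor = cols
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(
                    f"{path}:{lineno}: end < start (strand is explicit, not swapped)"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            preds.append(
                GenePrediction(
                    seq_id=seq_id,
                    interval=Interval(start - 1, end),
                    strand=strand,  # type: ignore[arg-type]
                    score=float(score_s),
                    predictor=predictor,
                )
            )
    return preds


def write_gene_calls(preds: Iterable[GenePrediction], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for p in preds:
            w.writerow(
                [p.seq_id, p.interval.start + 1, p.interval.end, p.strand, p.score, p.predictor]
            )


def tag_orfs(
    orfs: Iterable[OrfCall],
    preds: Iterable[GenePrediction],
    min_overlap_nt: int = 1,
) -> list[OrfCall]:
    """Tag each ORF that overlaps an ab-initio prediction on the same
    sequence and strand by at least ``min_overlap_nt``.

    Tagging is annotation-only: coordinates never change, and ORFs keep
    their full extent even past the prediction boundary.  The tag source is
    the prediction with the largest overlap (ties: higher score, then
    smaller start).  Untagged ORFs are retained with ``tagged=False``.
    """
    by_seq: dict[tuple[str, str], list[GenePrediction]] = {}
    for p in preds:
        by_seq.setdefault((p.seq_id, p.strand), []).append(p)
    out: list[OrfCall] = []
    for orf in orfs:
        best: tuple[int, float, int] | None = None
        best_pred: GenePrediction | None = None
        for p in by_seq.get((orf.seq_id, orf.strand), []):
            ov = orf.interval.intersection(p.interval)
            if ov < min_overlap_nt:
                continue
            key = (ov, p.score, -p.interval.start)
            if best is None or key > best:
                best, best_pred = key, p
        if best_pred is not None:
            out.append(replace(orf, tagged=True, tag_source=best_pred.pred_id))
        else:
            out.append(replace(orf, tagged=False, tag_source=None))
    return out


# ---------------------------------------------------------------------------
# Output


def emit_peptides(orfs: Iterable[OrfCall], tagged_only: bool = False) -> list[SeqRecord]:
    """Render ORF calls as peptide FASTA records.

    Record ids encode the genomic span: ``<seq_id>_<start1>_<end>_<strand><frame>``.
    Internal stops are impossible by construction; a terminal '*' (never
    produced by the ORF finder, whose spans exclude the stop codon) would be
    stripped defensively.
    """
    out: list[SeqRecord] = []
    for orf in orfs:
        if tagged_only and not orf.tagged:
            continue
        pep = orf.peptide.rstrip("*")
        if not pep:
            continue
        desc = []
        if orf.truncated_5p:
            desc.append("/5_prime_truncated")
        if orf.truncated_3p:
            desc.append("/3_prime_truncated")
        if orf.tag_source:
            desc.append(f"/tag={orf.tag_source}")
        out.append(SeqRecord(id=orf.orf_id, seq=pep, description=" ".join(desc)))
    return out


def write_orf_table(orfs: Iterable[OrfCall], path: str | Path) -> None:
    """ORF summary TSV with 1-based inclusive coordinates."""
    cols = [
        "orf_id", "seq_id", "start", "end", "strand", "frame",
        "truncated_5p", "truncated_3p", "masked_nt", "tagged", "tag_source",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for o in orfs:
            w.writerow(
                [
                    o.orf_id, o.seq_id, o.interval.start + 1, o.interval.end,
                    o.strand, o.frame, int(o.truncated_5p), int(o.truncated_3p),
                    o.masked_nt, int(o.tagged), o.tag_source or "",
                ]
            )
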