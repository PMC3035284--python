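"""The annotation value hierarchy and attribute assignment.

Each peptide's evidence bundle (BLAST classes, trusted HMM hits by isotype,
PRIAM enzyme profiles, transmembrane prediction, lipoprotein motif) is
ranked on a 25-level precedence table derived from extensive manual
curation of prokaryotic genomes.  The head of the ranked list names the
protein; gene symbol, EC number, GO terms and functional role category
follow their own, more nuanced precedence paths:

* gene symbol — an HMM model symbol when the hierarchy head is an HMM hit
  carrying one, otherwise the best curated BLAST subject among the stored
  top-10 hits;
* EC — TIGRFAM models first, then PRIAM profiles, then Pfam models;
* GO — TIGRFAM model terms, then terms implied by the assigned EC, then
  Pfam model terms, then the best curated BLAST subject's terms;
* role category — TIGRFAM models, then Pfam models.

PRIAM evidence assigns EC numbers only: it never supplies a common name or
symbol, so a PRIAM head falls through to the next name-eligible item.
Peptides with no rankable evidence are "hypothetical protein".
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .core_io import SeqRecord
from .evidence import (
    BlastClass,
    BlastHit,
    HmmHit,
    LipoMotifHit,
    PriamHit,
    TmhmmResult,
    classify_blast_hit,
    find_lipoprotein_motif,
    isotype_class,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HIERARCHY",
    "EvidenceBundle",
    "RankedEvidence",
    "Annotation",
    "MappingTables",
    "collect_bundles",
    "rank_bundle",
    "assign_common_name",
    "assign_gene_symbol",
    "assign_ec",
    "assign_go",
    "assign_role",
    "annotate",
    "annotation_header_fields",
    "write_annotation_fasta",
    "parse_annotation_header",
    "write_summary_tsv",
    "read_summary_tsv",
    "write_run_report",
    "HYPOTHETICAL_NAME",
    "DEFAULT_RANK",
]

HYPOTHETICAL_NAME = "hypothetical protein"
DEFAULT_RANK = 25

#: The annotation value hierarchy, verbatim: (rank, evidence type, evidence
#: class).  "TIGRfam Domain" appears at both rank 5 and rank 18 — a known
#: inconsistency of the curated table; the resolver assigns each item the
#: best (smallest) rank its class appears at.
HIERARCHY: tuple[tuple[int, str, str], ...] = (
    (1, "HMM", "TIGRfam Equivalog"),
    (2, "HMM", "Pfam Equivalog"),
    (3, "HMM", "TIGRfam Hypothetical Equivalog"),
    (4, "HMM", "Pfam Hypothetical Equivalog"),
    (5, "HMM", "TIGRfam Domain"),
    (6, "PRIAM", "PRIAM"),
    (7, "HMM", "TIGRfam Subfamily"),
    (8, "HMM", "TIGRfam Superfamily"),
    (9, "HMM", "TIGRfam EquivalogDomain"),
    (10, "HMM", "TIGRfam Hypothetical Equivalog Domain"),
    (11, "HMM", "TIGRfam Subfamily Domain"),
    (12, "HMM", "Pfam Subfamily"),
    (13, "HMM", "Pfam Superfamily"),
    (14, "HMM", "Pfam Equivalog Domain"),
    (15, "HMM", "Pfam Hypothetical Equivalog Domain"),
    (16, "HMM", "Pfam Subfamily Domain"),
    (17, "BLAST", "Panda BLASTP High Confidence"),
    (18, "HMM", "TIGRfam Domain"),
    (19, "HMM", "Pfam Domain"),
    (20, "HMM", "Pfam Uncharacterized"),
    (21, "BLAST", "Panda BLASTP Putative"),
    (22, "BLAST", "Panda BLASTP Conserved Domain"),
    (23, "TMHMM", "TMHMM"),
    (24, "LIPOPROTEIN", "Lipoprotein Motif"),
    (25, "DEFAULT", "Hypothetical"),
)

#: (evidence type, evidence class) -> best rank
_RANK_OF: dict[tuple[str, str], int] = {}
for _rank, _type, _class in HIERARCHY:
    _RANK_OF.setdefault((_type, _class), _rank)

#: library name as spelled in the hierarchy class labels
_LIB_LABEL = {"TIGRFAM": "TIGRfam", "PFAM": "Pfam"}

_BLAST_CLASS_LABEL = {
    BlastClass.HIGH_CONFIDENCE: "Panda BLASTP High Confidence",
    BlastClass.PUTATIVE: "Panda BLASTP Putative",
    BlastClass.CONSERVED_DOMAIN: "Panda BLASTP Conserved Domain",
    # Low Confidence has no hierarchy row: such hits never rank.
}


@dataclass
class EvidenceBundle:
    """All evidence collected for one peptide."""

    peptide_id: str
    peptide_len: int
    blast: list[tuple[BlastHit, BlastClass]] = field(default_factory=list)
    hmm: list[HmmHit] = field(default_factory=list)
    priam: list[PriamHit] = field(default_factory=list)
    tmhmm: TmhmmResult | None = None
    lipo: LipoMotifHit | None = None


@dataclass
class RankedEvidence:
    """An evidence item resolved to its hierarchy rank."""

    rank: int
    evidence_type: str  # HMM | BLAST | PRIAM | TMHMM | LIPOPROTEIN | DEFAULT
    evidence_class: str
    payload: object | None  # underlying hit; None for the DEFAULT sentinel

    #: PRIAM evidence contributes EC numbers only, never a name or symbol.
    @property
    def name_eligible(self) -> bool:
        return self.evidence_type != "PRIAM"


@dataclass
class Annotation:
    """The final functional attribute set for one peptide."""

    user_id: str
    peptide_id: str
    common_name: str
    common_name_ev: str
    gene_symbol: str = ""
    gene_symbol_ev: str = ""
    go_terms: list[str] = field(default_factory=list)
    go_ev: list[str] = field(default_factory=list)
    ec: str = ""
    ec_ev: str = ""
    role_id: str = ""
    role_ev: str = ""
    head_rank: int = DEFAULT_RANK


@dataclass
class MappingTables:
    """Immutable run-wide mappings (EC -> GO; model metadata travels on the
    hits themselves)."""

    ec_to_go: dict[str, tuple[str, ...]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Bundle assembly


def collect_bundles(
    peptides: Iterable[SeqRecord],
    blast: dict[str, list[BlastHit]] | None = None,
    hmm: dict[str, list[HmmHit]] | None = None,
    priam: dict[str, list[PriamHit]] | None = None,
    tmhmm: dict[str, TmhmmResult] | None = None,
    scan_lipoprotein: bool = True,
) -> list[EvidenceBundle]:
    """Join per-source evidence maps into one bundle per peptide.

    Evidence keyed to unknown peptides is a warning, not an error — partial
    evidence sets are normal for metagenomic runs.
    """
    blast = blast or {}
    hmm = hmm or {}
    priam = priam or {}
    tmhmm = tmhmm or {}
    bundles = []
    known = set()
    for pep in peptides:
        known.add(pep.id)
        plen = len(pep.seq)
        bundles.append(
            EvidenceBundle(
                peptide_id=pep.id,
                peptide_len=plen,
                blast=[(h, classify_blast_hit(h, plen)) for h in blast.get(pep.id, [])],
                hmm=list(hmm.get(pep.id, [])),
                priam=list(priam.get(pep.id, [])),
                tmhmm=tmhmm.get(pep.id),
                lipo=find_lipoprotein_motif(pep) if scan_lipoprotein else None,
            )
        )
    for source, keys in (("BLAST", blast), ("HMM", hmm), ("PRIAM", priam), ("TMHMM", tmhmm)):
        orphans = set(keys) - known
        if orphans:
            logger.warning("%d %s evidence keys match no peptide", len(orphans), source)
    return bundles


# ---------------------------------------------------------------------------
# Ranking


def hmm_hit_class(hit: HmmHit) -> str:
    """Hierarchy class label for an HMM hit, e.g. 'TIGRfam Equivalog'."""
    iso = isotype_class(hit.model)
    if iso == "Uncharacterized":
        return "Pfam Uncharacterized"
    label = f"{_LIB_LABEL[hit.model.library]} {iso}"
    # the hierarchy spells TIGRfam Equivalog Domain without the space
    if label == "TIGRfam Equivalog Domain":
        label = "TIGRfam EquivalogDomain"
    return label


def rank_bundle(b: EvidenceBundle, tmhmm_min_helices: int = 1) -> list[RankedEvidence]:
    """Resolve every evidence item to its hierarchy rank and sort.

    Items with no hierarchy row (Low Confidence BLAST hits, TMHMM results
    below the helix threshold) are excluded.  Sort order within a rank is
    (E-value ascending, score descending, subject/model id) for
    reproducibility.  A rank-25 DEFAULT sentinel is always appended, so the
    list is never empty and annotation is total.
    """
    entries: list[tuple[tuple, RankedEvidence]] = []

    for hit in b.hmm:
        label = hmm_hit_class(hit)
        rank = _RANK_OF.get(("HMM", label))
        if rank is None:
            logger.warning("HMM class %r has no hierarchy rank; skipped", label)
            continue
        key = (rank, hit.evalue, -hit.total_score, hit.model.model_id)
        entries.append((key, RankedEvidence(rank, "HMM", label, hit)))

    for hit, cls in b.blast:
        label = _BLAST_CLASS_LABEL.get(cls)
        if label is None:
            continue
        rank = _RANK_OF[("BLAST", label)]
        key = (rank, hit.evalue, -hit.bitscore, hit.subject_id)
        entries.append((key, RankedEvidence(rank, "BLAST", label, hit)))

    for hit in b.priam:
        rank = _RANK_OF[("PRIAM", "PRIAM")]
        key = (rank, hit.evalue, 0.0, hit.profile_id)
        entries.append((key, RankedEvidence(rank, "PRIAM", "PRIAM", hit)))

    if b.tmhmm is not None and b.tmhmm.predicted_helices >= tmhmm_min_helices:
        rank = _RANK_OF[("TMHMM", "TMHMM")]
        key = (rank, float("inf"), -float(b.tmhmm.predicted_helices), "TMHMM")
        entries.append((key, RankedEvidence(rank, "TMHMM", "TMHMM", b.tmhmm)))

    if b.lipo is not None:
        rank = _RANK_OF[("LIPOPROTEIN", "Lipoprotein Motif")]
        key = (rank, float("inf"), 0.0, "LIPO")
        entries.append((key, RankedEvidence(rank, "LIPOPROTEIN", "Lipoprotein Motif", b.lipo)))

    entries.sort(key=lambda e: e[0])
    ranked = [re for _, re in entries]
    ranked.append(RankedEvidence(DEFAULT_RANK, "DEFAULT", "Hypothetical", None))
    return ranked


def _evidence_string(item: RankedEvidence) -> str:
    if item.evidence_type == "HMM":
        return item.payload.model.model_id  # type: ignore[union-attr]
    if item.evidence_type == "BLAST":
        return item.payload.subject_id  # type: ignore[union-attr]
    if item.evidence_type == "PRIAM":
        return item.payload.profile_id  # type: ignore[union-attr]
    if item.evidence_type == "TMHMM":
        return "TMHMM"
    if item.evidence_type == "LIPOPROTEIN":
        return "LIPO"
    return "DEFAULT"


# ---------------------------------------------------------------------------
# Attribute assignment


def assign_common_name(ranked: list[RankedEvidence]) -> tuple[str, str]:
    """Name the protein from the best-ranked name-eligible evidence item."""
    for item in ranked:
        if not item.name_eligible:
            continue
        if item.evidence_type == "HMM":
            name = item.payload.model.name or item.payload.model.model_id  # type: ignore[union-attr]
        elif item.evidence_type == "BLAST":
            hit: BlastHit = item.payload  # type: ignore[assignment]
            name = hit.subject_name or hit.subject_id
        elif item.evidence_type == "TMHMM":
            name = "putative membrane protein"
        elif item.evidence_type == "LIPOPROTEIN":
            name = "putative lipoprotein"
        else:  # DEFAULT
            name = HYPOTHETICAL_NAME
        return name, _evidence_string(item)
    return HYPOTHETICAL_NAME, "DEFAULT"  # unreachable: sentinel is eligible


def assign_gene_symbol(b: EvidenceBundle, ranked: list[RankedEvidence]) -> tuple[str, str]:
    """Gene symbol: hierarchy primacy for HMM model symbols, otherwise the
    best curated BLAST subject among the stored top-10 hits."""
    head = ranked[0]
    if head.evidence_type == "HMM" and head.payload.model.symbol:  # type: ignore[union-attr]
        return head.payload.model.symbol, head.payload.model.model_id  # type: ignore[union-attr]
    for item in ranked:
        if item.evidence_type != "BLAST":
            continue
        hit: BlastHit = item.payload  # type: ignore[assignment]
        if hit.subject_is_curated and hit.subject_symbol:
            return hit.subject_symbol, hit.subject_id
    return "", ""


def _best_hmm_with(b: EvidenceBundle, library: str, attr: str) -> HmmHit | None:
    """Best trusted hit (E-value, then score) from one library whose model
    carries a non-empty ``attr``."""
    cands = [
        h
        for h in b.hmm
        if h.model.library == library and getattr(h.model, attr) not in ((), None, "")
    ]
    cands.sort(key=lambda h: (h.evalue, -h.total_score, h.model.model_id))
    return cands[0] if cands else None


def assign_ec(b: EvidenceBundle) -> tuple[str, str]:
    """EC precedence: TIGRFAM model > PRIAM profile > Pfam model."""
    hit = _best_hmm_with(b, "TIGRFAM", "ec")
    if hit is not None:
        return " // ".join(hit.model.ec), hit.model.model_id
    if b.priam:
        best = min(b.priam, key=lambda h: (h.evalue, h.profile_id))
        ecs = {h.ec for h in b.priam if h.evalue == best.evalue}
        if len(ecs) > 1:
            logger.warning("peptide %s: conflicting PRIAM ECs %s; best profile wins", b.peptide_id, sorted(ecs))
        return best.ec, best.profile_id
    hit = _best_hmm_with(b, "PFAM", "ec")
    if hit is not None:
        return " // ".join(hit.model.ec), hit.model.model_id
    return "", ""


def assign_go(b: EvidenceBundle, maps: MappingTables) -> tuple[list[str], list[str]]:
    """GO evidence order: TIGRFAM model, assigned EC, Pfam model, curated
    BLAST subject.  The first source with terms wins; terms are
    deduplicated preserving order, evidence repeated per term."""
    hit = _best_hmm_with(b, "TIGRFAM", "go")
    if hit is not None:
        terms = _dedup(hit.model.go)
        return terms, [hit.model.model_id] * len(terms)

    ec, _ec_ev = assign_ec(b)
    if ec:
        terms = []
        for one in ec.split(" // "):
            terms.extend(maps.ec_to_go.get(one, ()))
        terms = _dedup(terms)
        if terms:
            return terms, [ec] * len(terms)

    hit = _best_hmm_with(b, "PFAM", "go")
    if hit is not None:
        terms = _dedup(hit.model.go)
        return terms, [hit.model.model_id] * len(terms)

    for h in b.blast:
        hit_b, _cls = h
        if hit_b.subject_is_curated and hit_b.subject_go:
            terms = _dedup(hit_b.subject_go)
            return terms, [hit_b.subject_id] * len(terms)
    return [], []


def assign_role(b: EvidenceBundle) -> tuple[str, str]:
    """Functional role category: TIGRFAM models in preference to Pfam."""
    for library in ("TIGRFAM", "PFAM"):
        hit = _best_hmm_with(b, library, "role_id")
        if hit is not None:
            return str(hit.model.role_id), hit.model.model_id
    return "", ""


def _dedup(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def annotate(
    b: EvidenceBundle, maps: MappingTables | None = None, user_id: str | None = None
) -> Annotation:
    """Compose the five attribute assignments into one Annotation.

    Pure and deterministic for a fixed bundle.
    """
    maps = maps or MappingTables()
    ranked = rank_bundle(b)
    name, name_ev = assign_common_name(ranked)
    symbol, symbol_ev = assign_gene_symbol(b, ranked)
    ec, ec_ev = assign_ec(b)
    go_terms, go_ev = assign_go(b, maps)
    role, role_ev = assign_role(b)
    return Annotation(
        user_id=user_id if user_id is not None else b.peptide_id,
        peptide_id=b.peptide_id,
        common_name=name,
        common_name_ev=name_ev,
        gene_symbol=symbol,
        gene_symbol_ev=symbol_ev,
        go_terms=go_terms,
        go_ev=go_ev,
        ec=ec,
        ec_ev=ec_ev,
        role_id=role,
        role_ev=role_ev,
        head_rank=ranked[0].rank,
    )


# ---------------------------------------------------------------------------
# Output formats

#: column order of the annotation header / summary table
SUMMARY_COLUMNS = [
    "user_id",
    "peptide_id",
    "common_name_marker",
    "common_name",
    "common_name_evidence",
    "gene_symbol_marker",
    "gene_symbol",
    "gene_symbol_evidence",
    "go_marker",
    "go_terms",
    "go_evidence",
    "ec_marker",
    "ec_id",
    "ec_evidence",
    "role_marker",
    "role_id",
    "role_evidence",
]

_JOIN = " // "


def annotation_header_fields(a: Annotation) -> list[str]:
    """The 17 tab-separated header fields, section markers included."""
    return [
        a.user_id,
        a.peptide_id,
        "common_name",
        a.common_name,
        a.common_name_ev,
        "gene_symbol",
        a.gene_symbol,
        a.gene_symbol_ev,
        "GO",
        _JOIN.join(a.go_terms),
        _JOIN.join(a.go_ev),
        "EC",
        a.ec,
        a.ec_ev,
        "TIGR_role",
        a.role_id,
        a.role_ev,
    ]


def write_annotation_fasta(
    annotations: Iterable[Annotation],
    peptides: Iterable[SeqRecord],
    path: str | Path,
) -> None:
    """Annotated peptide multi-FASTA: the header carries the full attribute
    set as tab-delimited fields with literal section markers; empty
    attributes keep their (empty) field so the format stays positional."""
    peps = {p.id: p for p in peptides}
    with open(path, "w") as fh:
        for a in annotations:
            pep = peps.get(a.peptide_id)
            if pep is None:
                raise ValueError(f"annotation for unknown peptide {a.peptide_id!r}")
            fh.write(">" + "\t".join(annotation_header_fields(a)) + "\n")
            for i in range(0, len(pep.seq), 60):
                fh.write(pep.seq[i : i + 60] + "\n")


def parse_annotation_header(header: str) -> Annotation:
    """Inverse of :func:`annotation_header_fields` (header without '>')."""
    fields = header.split("\t")
    if len(fields) != 17:
        raise ValueError(f"expected 17 header fields, got {len(fields)}")
    for idx, marker in ((2, "common_name"), (5, "gene_symbol"), (8, "GO"), (11, "EC"), (14, "TIGR_role")):
        if fields[idx] != marker:
            raise ValueError(f"field {idx}: expected marker {marker!r}, got {fields[idx]!r}")
    return Annotation(
        user_id=fields[0],
        peptide_id=fields[1],
        common_name=fields[3],
        common_name_ev=fields[4],
        gene_symbol=fields[6],
        gene_symbol_ev=fields[7],
        go_terms=[t for t in fields[9].split(_JOIN) if t],
        go_ev=[t for t in fields[10].split(_JOIN) if t],
        ec=fields[12],
        ec_ev=fields[13],
        role_id=fields[15],
        role_ev=fields[16],
    )


def write_summary_tsv(annotations: Iterable[Annotation], path: str | Path) -> None:
    """Flat-file annotation summary: header row plus one row per peptide,
    UTF-8, LF line endings."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SUMMARY_COLUMNS)
        for a in annotations:
            w.writerow(annotation_header_fields(a))


def read_summary_tsv(path: str | Path) -> list[Annotation]:
    out: list[Annotation] = []
    with open(path, encoding="utf-8") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header != SUMMARY_COLUMNS:
            raise ValueError("unrecognized summary header")
        for row in r:
            out.append(parse_annotation_header("\t".join(row)))
    return out


def write_run_report(annotations: list[Annotation], path: str | Path) -> None:
    """Plain-text run report: totals and counts per hierarchy rank."""
    by_rank: dict[int, int] = {}
    for a in annotations:
        by_rank[a.head_rank] = by_rank.get(a.head_rank, 0) + 1
    class_of = {r: (t, c) for r, t, c in HIERARCHY}
    with open(path, "w") as fh:
        fh.write(f"peptides annotated\t{len(annotations)}\n")
        hypo = by_rank.get(DEFAULT_RANK, 0)
        fh.write(f"hypothetical\t{hypo}\n")
        for rank in sorted(by_rank):
            t, c = class_of[rank]
            fh.write(f"rank {rank}\t{t}\t{c}\t{by_rank[rank]}\n")
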