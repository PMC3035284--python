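"""Functional-annotation evidence: parsing and classification.

Every homology or motif search feeding the annotation hierarchy is parsed
here into typed hits, with the filtering the pipeline applies at collection
time: the BLASTP E-value ceiling (1e-5) and top-10 retention, per-model HMM
trusted cutoffs, the PRIAM 1e-10 ceiling, TMHMM helix extraction, and the
prolipoprotein signal-peptide (lipobox) scan.

BLAST hits are graded into four confidence classes on the percent-identity
x query-coverage plane:

=================  ==========================================
High Confidence    identity >= 35% and coverage >= 85%
Conserved Domain   identity >= 35% and coverage <  85%
Putative           identity <  35% and coverage >= 80%
Low Confidence     identity <  35% and coverage <  80%
=================  ==========================================

Coverage is the aligned fraction of the *query* peptide: queries are
fragments, and the classes grade how much of the fragment is supported.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from .core_io import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BlastHit",
    "BlastClass",
    "HmmModelMeta",
    "HmmHit",
    "PriamHit",
    "TmhmmResult",
    "LipoMotifHit",
    "parse_blast_tabular",
    "classify_blast_hit",
    "parse_hmm_hits",
    "isotype_class",
    "parse_priam",
    "parse_tmhmm",
    "find_lipoprotein_motif",
    "load_model_meta",
    "load_curated_subjects",
    "load_profile_to_ec",
    "load_ec_to_go",
    "CuratedSubject",
    "DEFAULT_BLAST_EVALUE",
    "DEFAULT_BLAST_TOP_N",
    "DEFAULT_PRIAM_EVALUE",
    "DEFAULT_LIPOBOX_PATTERN",
    "LIPOBOX_WINDOW",
    "EC_PATTERN",
]

#: collection-time defaults
DEFAULT_BLAST_EVALUE = 1e-5
DEFAULT_BLAST_TOP_N = 10
DEFAULT_PRIAM_EVALUE = 1e-10

#: EC numbers: four fields, trailing fields may be undetermined ('-')
EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")

#: Prokaryotic lipobox: [hydrophobic][small/hydrophobic][A/G/S] followed by
#: the invariant cysteine that is lipidated.  Scanned within the first
#: LIPOBOX_WINDOW residues (the signal-peptide region).
DEFAULT_LIPOBOX_PATTERN = r"[LIVMFWSTAG][LIVMFYSTAGCQ][AGS]C"
LIPOBOX_WINDOW = 35


class BlastClass(Enum):
    HIGH_CONFIDENCE = "High Confidence"
    PUTATIVE = "Putative"
    CONSERVED_DOMAIN = "Conserved Domain"
    LOW_CONFIDENCE = "Low Confidence"


@dataclass
class BlastHit:
    """One row of BLAST tabular output (coordinates 1-based inclusive, as
    printed by BLAST), optionally decorated with curated-subject metadata."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_is_curated: bool = False
    subject_symbol: str | None = None
    subject_go: list[str] | None = None
    subject_name: str | None = None


@dataclass(frozen=True)
class HmmModelMeta:
    """Per-model metadata: library, isotype, trusted cutoff and the
    functional attributes the model can transfer."""

    model_id: str
    library: str  # TIGRFAM | PFAM
    isotype: str | None
    trusted_cutoff: float
    name: str = ""
    symbol: str | None = None
    ec: tuple[str, ...] = ()
    go: tuple[str, ...] = ()
    role_id: int | None = None


@dataclass
class HmmHit:
    query_id: str
    model: HmmModelMeta
    total_score: float
    evalue: float


@dataclass
class PriamHit:
    query_id: str
    ec: str
    evalue: float
    profile_id: str


@dataclass
class TmhmmResult:
    query_id: str
    predicted_helices: int
    exp_aa_in_membrane: float


@dataclass
class LipoMotifHit:
    query_id: str
    match_start: int  # 0-based residue offset
    matched_seq: str


@dataclass(frozen=True)
class CuratedSubject:
    """Sidecar metadata for a curated reference protein (symbol/GO donor)."""

    subject_id: str
    symbol: str | None
    name: str | None
    go: tuple[str, ...]


# ---------------------------------------------------------------------------
# BLAST


def _split_multi(cell: str) -> tuple[str, ...]:
    return tuple(t for t in (p.strip() for p in cell.split("//")) if t)


def parse_blast_tabular(
    path: str | Path,
    top_n: int = DEFAULT_BLAST_TOP_N,
    max_evalue: float = DEFAULT_BLAST_EVALUE,
    curated: dict[str, CuratedSubject] | None = None,
) -> dict[str, list[BlastHit]]:
    """Parse BLAST tabular (-m 8) output.

    Per query, hits above ``max_evalue`` are dropped, the rest sorted by
    (E-value ascending, bit score descending) and truncated to the
    ``top_n`` most significant alignments.  When a curated-subject map is
    supplied, matching subjects are flagged and decorated with symbol, name
    and GO terms.
    """
    by_query: dict[str, list[BlastHit]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                hit = BlastHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_len=int(cols[3]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if hit.evalue > max_evalue:
                continue
            if curated is not None and hit.subject_id in curated:
                meta = curated[hit.subject_id]
                hit.subject_is_curated = True
                hit.subject_symbol = meta.symbol
                hit.subject_name = meta.name
                hit.subject_go = list(meta.go)
            by_query.setdefault(hit.query_id, []).append(hit)
    for qid, hits in by_query.items():
        hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        del hits[top_n:]
    return by_query


def classify_blast_hit(hit: BlastHit, query_len: int) -> BlastClass:
    """Grade a hit on the identity x query-coverage plane (total: every hit
    receives exactly one class)."""
    if query_len < 1:
        raise ValueError("query_len must be >= 1")
    cov = (hit.q_end - hit.q_start + 1) / query_len * 100.0
    if hit.pct_identity >= 35.0:
        return BlastClass.HIGH_CONFIDENCE if cov >= 85.0 else BlastClass.CONSERVED_DOMAIN
    return BlastClass.PUTATIVE if cov >= 80.0 else BlastClass.LOW_CONFIDENCE


# ---------------------------------------------------------------------------
# HMM


def parse_hmm_hits(
    path: str | Path, meta: dict[str, HmmModelMeta]
) -> dict[str, list[HmmHit]]:
    """Parse the canonical HMM hit TSV (query_id, model_id, total bit score,
    E-value), keeping only hits at or above their model's trusted cutoff.

    Hits against models absent from the metadata table are dropped with a
    warning — without a cutoff they cannot be trusted.
    """
    by_query: dict[str, list[HmmHit]] = {}
    unknown = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            qid, model_id, score_s, evalue_s = cols
            m = meta.get(model_id)
            if m is None:
                unknown += 1
                logger.warning("%s:%d: unknown HMM model %s dropped", path, lineno, model_id)
                continue
            score, evalue = float(score_s), float(evalue_s)
            if score < m.trusted_cutoff:
                continue
            by_query.setdefault(qid, []).append(
                HmmHit(query_id=qid, model=m, total_score=score, evalue=evalue)
            )
    if unknown:
        logger.warning("%s: %d hits against unknown models dropped", path, unknown)
    for hits in by_query.values():
        hits.sort(key=lambda h: (h.evalue, -h.total_score, h.model.model_id))
    return by_query


#: isotype string -> hierarchy class label (per library where they differ)
_ISOTYPE_CLASS = {
    "equivalog": "Equivalog",
    "equivalog_domain": "Equivalog Domain",
    "hypoth_equivalog": "Hypothetical Equivalog",
    "hypoth_equivalog_domain": "Hypothetical Equivalog Domain",
    "domain": "Domain",
    "subfamily": "Subfamily",
    "subfamily_domain": "Subfamily Domain",
    "superfamily": "Superfamily",
    "uncharacterized": "Uncharacterized",
}


def isotype_class(meta: HmmModelMeta) -> str:
    """Map a model's (library, isotype) to its hierarchy class label.

    Pfam models without an assignable isotype are Uncharacterized.
    """
    if meta.isotype is None or meta.isotype == "":
        if meta.library == "PFAM":
            return "Uncharacterized"
        raise ValueError(f"model {meta.model_id}: {meta.library} model lacks an isotype")
    try:
        return _ISOTYPE_CLASS[meta.isotype]
    except KeyError:
        raise ValueError(f"model {meta.model_id}: unknown isotype {meta.isotype!r}") from None


# ---------------------------------------------------------------------------
# PRIAM


def parse_priam(
    path: str | Path,
    profile_to_ec: dict[str, str],
    max_evalue: float = DEFAULT_PRIAM_EVALUE,
) -> dict[str, list[PriamHit]]:
    """Parse PRIAM RPS-BLAST tabular output (-m 8).

    The subject column carries the enzyme profile id; a sidecar map resolves
    it to an EC number.  Hits above ``max_evalue`` are dropped; each query's
    hits are sorted by E-value.
    """
    by_query: dict[str, list[PriamHit]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise ValueError(f"{path}:{lineno}: expected >=11 columns, got {len(cols)}")
            qid, profile_id, evalue = cols[0], cols[1], float(cols[10])
            if evalue > max_evalue:
                continue
            ec = profile_to_ec.get(profile_id)
            if ec is None:
                logger.warning("%s:%d: profile %s has no EC mapping", path, lineno, profile_id)
                continue
            if not EC_PATTERN.match(ec):
                raise ValueError(f"{path}:{lineno}: malformed EC number {ec!r}")
            by_query.setdefault(qid, []).append(
                PriamHit(query_id=qid, ec=ec, evalue=evalue, profile_id=profile_id)
            )
    for hits in by_query.values():
        hits.sort(key=lambda h: (h.evalue, h.profile_id))
    return by_query


# ---------------------------------------------------------------------------
# TMHMM

_TMHMM_FIELD = re.compile(r"(\w+)=([^\s]+)")


def parse_tmhmm(path: str | Path) -> dict[str, TmhmmResult]:
    """Parse TMHMM short-format output (one line per protein with
    ``len= ExpAA= First60= PredHel= Topology=`` fields)."""
    results: dict[str, TmhmmResult] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            qid = line.split()[0]
            fields = dict(_TMHMM_FIELD.findall(line))
            if "PredHel" not in fields:
                raise ValueError(f"{path}:{lineno}: missing PredHel field")
            if qid in results:
                logger.warning("%s:%d: duplicate TMHMM record for %s; last wins", path, lineno, qid)
            results[qid] = TmhmmResult(
                query_id=qid,
                predicted_helices=int(fields["PredHel"]),
                exp_aa_in_membrane=float(fields.get("ExpAA", "0")),
            )
    return results


# ---------------------------------------------------------------------------
# Lipoprotein motif


def find_lipoprotein_motif(
    peptide: SeqRecord,
    pattern: str = DEFAULT_LIPOBOX_PATTERN,
    window: int = LIPOBOX_WINDOW,
) -> LipoMotifHit | None:
    """Scan the N-terminal signal region for a lipobox.

    The motif (ending in the invariant, lipidated cysteine) must lie wholly
    within the first ``window`` residues; the first match is returned.
    """
    if not peptide.seq:
        raise ValueError("empty peptide")
    m = re.search(pattern, peptide.seq.upper()[:window])
    if m is None:
        return None
    return LipoMotifHit(query_id=peptide.id, match_start=m.start(), matched_seq=m.group(0))


# ---------------------------------------------------------------------------
# Mapping-table loaders (all plain TSV; multi-values joined by '//')


def load_model_meta(path: str | Path) -> dict[str, HmmModelMeta]:
    """Model metadata TSV: model_id, library, isotype, trusted_cutoff, name,
    symbol, ec ('//'-joined), go ('//'-joined), role_id."""
    meta: dict[str, HmmModelMeta] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            model_id, library, isotype, tc, name, symbol, ec, go, role = cols
            if library not in ("TIGRFAM", "PFAM"):
                raise ValueError(f"{path}:{lineno}: unknown library {library!r}")
            meta[model_id] = HmmModelMeta(
                model_id=model_id,
                library=library,
                isotype=isotype or None,
                trusted_cutoff=float(tc),
                name=name,
                symbol=symbol or None,
                ec=_split_multi(ec),
                go=_split_multi(go),
                role_id=int(role) if role else None,
            )
    return meta


def load_curated_subjects(path: str | Path) -> dict[str, CuratedSubject]:
    """Curated-subject sidecar TSV: subject_id, symbol, name, go ('//'-joined)."""
    out: dict[str, CuratedSubject] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            sid, symbol, name, go = cols
            out[sid] = CuratedSubject(
                subject_id=sid, symbol=symbol or None, name=name or None, go=_split_multi(go)
            )
    return out


def load_profile_to_ec(path: str | Path) -> dict[str, str]:
    """PRIAM sidecar TSV: profile_id, EC."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            out[cols[0]] = cols[1]
    return out


def load_ec_to_go(path: str | Path) -> dict[str, tuple[str, ...]]:
    """EC-to-GO mapping TSV: ec, go ('//'-joined)."""
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            out[cols[0]] = _split_multi(cols[1])
    return out
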