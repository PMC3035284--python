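"""Self-contained synthetic data with planted ground truth.

Generates everything the pipeline consumes — genomes with planted
protein-coding genes and ncRNAs, shotgun-style reads, and mock homology
evidence in the exact file dialects the parsers read — so every stage is
testable end-to-end without external databases or searches.

Planted genes are in-frame, internally stop-free spans with an ATG start
and a terminal stop, sized around the ~900 bp typical bacterial gene and
never below the 180-nt annotation minimum.  Each gene is preceded by an
in-frame stop "guard" so the naive ORF finder recovers exactly the planted
coding span.  Gene N-termini are generated cysteine-free so that a planted
gene can only match the lipoprotein motif when a test plants one
deliberately.  Intergenic sequence is uniform-random (GC 50% by default),
which carries stop codons in all frames at natural density.

Mock evidence realizes a chosen hierarchy tier per gene: e.g. tier 1
produces a TIGRFAM equivalog hit above its trusted cutoff, tier 17 a BLAST
hit at >=35% identity over >=85% of the query.  The truth table records,
per gene, the attribute values the annotator is expected to reproduce —
for tiers whose evidence type cannot name a protein (PRIAM, rank 6) the
expected name is "hypothetical protein" with the planted EC still
recovered.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from .core_io import Interval, SeqRecord, revcomp, translate, CodonTable
from .annotator import HYPOTHETICAL_NAME

__all__ = [
    "SynthConfig",
    "TruthGene",
    "TruthNcrna",
    "TruthTable",
    "EvidenceFiles",
    "generate_genomes",
    "fragment_reads",
    "mock_evidence",
    "write_truth_table",
    "HMM_TIER_MODEL",
]

_SENSE_CODONS: tuple[str, ...] = ()
_SENSE_NO_CYS: tuple[str, ...] = ()


def _codon_sets() -> tuple[tuple[str, ...], tuple[str, ...]]:
    global _SENSE_CODONS, _SENSE_NO_CYS
    if not _SENSE_CODONS:
        t = CodonTable.from_ncbi(11)
        sense = sorted(c for c in t.forward)
        _SENSE_CODONS = tuple(sense)
        _SENSE_NO_CYS = tuple(c for c in sense if t.forward[c] != "C")
    return _SENSE_CODONS, _SENSE_NO_CYS


#: hierarchy rank -> (library, isotype) for HMM-realizable tiers
HMM_TIER_MODEL: dict[int, tuple[str, str]] = {
    1: ("TIGRFAM", "equivalog"),
    2: ("PFAM", "equivalog"),
    3: ("TIGRFAM", "hypoth_equivalog"),
    4: ("PFAM", "hypoth_equivalog"),
    5: ("TIGRFAM", "domain"),
    7: ("TIGRFAM", "subfamily"),
    8: ("TIGRFAM", "superfamily"),
    9: ("TIGRFAM", "equivalog_domain"),
    10: ("TIGRFAM", "hypoth_equivalog_domain"),
    11: ("TIGRFAM", "subfamily_domain"),
    12: ("PFAM", "subfamily"),
    13: ("PFAM", "superfamily"),
    14: ("PFAM", "equivalog_domain"),
    15: ("PFAM", "hypoth_equivalog_domain"),
    16: ("PFAM", "subfamily_domain"),
    18: ("TIGRFAM", "domain"),
    19: ("PFAM", "domain"),
    20: ("PFAM", "uncharacterized"),
}

#: tiers realized through BLAST fixtures: (pct identity, query coverage %)
BLAST_TIER_PARAMS = {17: (90.0, 100), 21: (30.0, 90), 22: (90.0, 50)}


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    ``gene_density`` is genes per kb; ``ncrna_rate`` is planted ncRNA loci
    per genome.  ``seed`` fixes every output byte-for-byte.
    """

    n_genomes: int = 2
    genome_len_nt: int = 12_000
    gene_density: float = 0.8
    mean_gene_len_nt: int = 900
    ncrna_rate: float = 1.0
    read_len_nt: int = 900
    n_reads: int = 100
    seed: int = 0
    add_clear_ranges: bool = False


@dataclass
class TruthGene:
    """One planted gene with the annotation the pipeline should recover."""

    gene_id: str
    genome_id: str
    interval: Interval  # coding span, stop codon excluded, forward coords
    strand: str
    peptide: str
    name: str
    symbol: str
    ec: str
    go: tuple[str, ...]
    role_id: int
    tier: int | None = None
    expected: dict[str, object] = field(default_factory=dict)


@dataclass
class TruthNcrna:
    ncrna_id: str
    genome_id: str
    interval: Interval
    strand: str
    kind: str  # tRNA | rRNA


@dataclass
class TruthTable:
    genes: list[TruthGene] = field(default_factory=list)
    ncrnas: list[TruthNcrna] = field(default_factory=list)


@dataclass
class EvidenceFiles:
    """Paths of the mock evidence file set."""

    blast: Path
    curated: Path
    hmm: Path
    model_meta: Path
    priam: Path
    priam_ec: Path
    tmhmm: Path


# ---------------------------------------------------------------------------
# Genome generation


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choices("ACGT", k=n))


def _gene_cassette(rng: random.Random, coding_len: int) -> tuple[str, str]:
    """An in-frame stop guard + gene (ATG..body) + stop codon.

    ``coding_len`` counts the span from ATG through the last sense codon
    (multiple of 3).  Returns (cassette nt, peptide).  The first 35 codons
    carry no cysteine, keeping the lipobox scan window clear of spurious
    motif matches.
    """
    if coding_len % 3 or coding_len < 6:
        raise ValueError("coding_len must be a multiple of 3, >= 6")
    sense, no_cys = _codon_sets()
    n_body = coding_len // 3 - 1
    # keep the whole lipobox scan window cysteine-free
    body = [rng.choice(no_cys if i < 35 else sense) for i in range(n_body)]
    gene = "ATG" + "".join(body)
    table = CodonTable.from_ncbi(11)
    peptide = translate(gene, table, 1)
    stop = rng.choice(sorted(table.stops))
    return "TAA" + gene + stop, peptide


def generate_genomes(cfg: SynthConfig) -> tuple[list[SeqRecord], TruthTable]:
    """Generate genomes with planted genes and ncRNAs plus their truth.

    Elements (gene cassettes, ncRNA blocks) are laid out left to right with
    random intergenic spacers; an infeasible gene density raises.
    """
    rng = random.Random(cfg.seed)
    truth = TruthTable()
    genomes: list[SeqRecord] = []
    gene_no = 0
    for g in range(cfg.n_genomes):
        gid = f"syng{g:03d}"
        n_genes = round(cfg.gene_density * cfg.genome_len_nt / 1000)
        n_ncrna = round(cfg.ncrna_rate)

        elements: list[tuple[str, object]] = []  # (kind, payload)
        for _ in range(n_genes):
            coding = max(180, round(rng.gauss(cfg.mean_gene_len_nt, cfg.mean_gene_len_nt / 4) / 3) * 3)
            cassette, peptide = _gene_cassette(rng, coding)
            strand = rng.choice("+-")
            elements.append(("gene", (cassette, peptide, strand, coding)))
        for k in range(n_ncrna):
            kind = "tRNA" if k % 2 == 0 else "rRNA"
            length = 75 if kind == "tRNA" else rng.randrange(110, 160)
            strand = rng.choice("+-")
            elements.append(("ncrna", (_random_seq(rng, length), kind, strand)))
        rng.shuffle(elements)

        min_gap = 25
        used = sum(
            len(p[0]) for _, p in elements
        ) + min_gap * (len(elements) + 1)
        if used > cfg.genome_len_nt:
            raise ValueError(
                f"infeasible density: {used} nt of elements+gaps > genome length "
                f"{cfg.genome_len_nt}"
            )
        slack = cfg.genome_len_nt - used
        cuts = sorted(rng.randrange(slack + 1) for _ in range(len(elements)))
        gaps = (
            [min_gap + cuts[0]]
            + [min_gap + (b - a) for a, b in zip(cuts[:-1], cuts[1:])]
            + [min_gap + (slack - cuts[-1])]
            if elements
            else [cfg.genome_len_nt]
        )

        parts: list[str] = []
        pos = 0
        for gap, (kind, payload) in zip(gaps, elements):
            parts.append(_random_seq(rng, gap))
            pos += gap
            if kind == "gene":
                cassette, peptide, strand, coding = payload  # type: ignore[misc]
                block = cassette if strand == "+" else revcomp(cassette)
                # coding span sits 3 nt in from each cassette end, both strands
                iv = Interval(pos + 3, pos + 3 + coding)
                truth.genes.append(
                    TruthGene(
                        gene_id=f"sg{gene_no:04d}",
                        genome_id=gid,
                        interval=iv,
                        strand=strand,
                        peptide=peptide if strand == "+" else peptide,
                        name=f"synthetic protein {gene_no}",
                        symbol=f"syn{chr(ord('A') + gene_no % 26)}{gene_no}",
                        ec=f"{1 + gene_no % 6}.{1 + gene_no % 9}.{1 + gene_no % 9}.{1 + gene_no % 20}",
                        go=(f"GO:{7000000 + gene_no:07d}", f"GO:{7100000 + gene_no:07d}"),
                        role_id=100 + gene_no % 30,
                    )
                )
                gene_no += 1
            else:
                seq, nkind, strand = payload  # type: ignore[misc]
                iv = Interval(pos, pos + len(seq))
                truth.ncrnas.append(
                    TruthNcrna(
                        ncrna_id=f"sn{len(truth.ncrnas):04d}",
                        genome_id=gid,
                        interval=iv,
                        strand=strand,
                        kind=nkind,
                    )
                )
                block = seq
            parts.append(block)
            pos += len(block)
        parts.append(_random_seq(rng, cfg.genome_len_nt - pos))
        genomes.append(SeqRecord(id=gid, seq="".join(parts), description="/synthetic"))
    return genomes, truth


def fragment_reads(genomes: list[SeqRecord], cfg: SynthConfig) -> list[SeqRecord]:
    """Uniformly placed, randomly stranded substrings emulating shotgun
    reads; headers record provenance for truth lookup."""
    rng = random.Random(cfg.seed + 1)
    for g in genomes:
        if cfg.read_len_nt > len(g.seq):
            raise ValueError(
                f"read length {cfg.read_len_nt} exceeds genome {g.id} length {len(g.seq)}"
            )
    reads: list[SeqRecord] = []
    for i in range(cfg.n_reads):
        g = genomes[rng.randrange(len(genomes))]
        start = rng.randrange(len(g.seq) - cfg.read_len_nt + 1)
        strand = rng.choice("+-")
        seq = g.seq[start : start + cfg.read_len_nt]
        if strand == "-":
            seq = revcomp(seq)
        desc = f"/genome={g.id} /gstart={start + 1} /gstrand={strand}"
        if cfg.add_clear_ranges:
            trim = max(1, cfg.read_len_nt // 20)
            desc += f" /clear_range={trim + 1}-{cfg.read_len_nt - trim}"
        reads.append(SeqRecord(id=f"read{i:05d}", seq=seq, description=desc))
    return reads


# ---------------------------------------------------------------------------
# Mock evidence


def _expected_for_tier(g: TruthGene, tier: int) -> dict[str, object]:
    if tier in HMM_TIER_MODEL:
        return {
            "name": g.name,
            "symbol": g.symbol,
            "ec": g.ec,
            "go": list(g.go),
            "role": str(g.role_id),
        }
    if tier in BLAST_TIER_PARAMS:
        return {"name": g.name, "symbol": g.symbol, "ec": "", "go": list(g.go), "role": ""}
    if tier == 6:
        return {"name": HYPOTHETICAL_NAME, "symbol": "", "ec": g.ec, "go": [], "role": ""}
    if tier == 23:
        return {"name": "putative membrane protein", "symbol": "", "ec": "", "go": [], "role": ""}
    if tier == 25:
        return {"name": HYPOTHETICAL_NAME, "symbol": "", "ec": "", "go": [], "role": ""}
    raise ValueError(f"no mock-evidence generator realizes tier {tier}")


def mock_evidence(
    peptides: list[SeqRecord],
    truth: TruthTable,
    tier_plan: list[int],
    out_dir: str | Path,
) -> EvidenceFiles:
    """Write an evidence file set realizing one hierarchy tier per planted
    gene (``tier_plan`` is cycled across genes in truth-table order).

    Peptides are matched to planted genes by amino-acid sequence; genes with
    no matching peptide get no evidence.  Updates each gene's ``tier`` and
    ``expected`` attributes in place.  Tier 24 (the lipoprotein motif) is
    sequence-intrinsic and cannot be realized by an evidence file — plant
    the motif in the gene instead.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = EvidenceFiles(
        blast=out / "blast.m8",
        curated=out / "curated_subjects.tsv",
        hmm=out / "hmm_hits.tsv",
        model_meta=out / "model_meta.tsv",
        priam=out / "priam.m8",
        priam_ec=out / "priam_profile_ec.tsv",
        tmhmm=out / "tmhmm.txt",
    )
    by_pep = {p.seq: p for p in peptides}

    blast_lines: list[str] = []
    curated_lines: list[str] = []
    hmm_lines: list[str] = []
    meta_lines: list[str] = []
    priam_lines: list[str] = []
    priam_ec_lines: list[str] = []
    tmhmm_lines: list[str] = []

    for i, g in enumerate(truth.genes):
        tier = tier_plan[i % len(tier_plan)]
        g.tier = tier
        g.expected = _expected_for_tier(g, tier)
        pep = by_pep.get(g.peptide)
        if pep is None:
            g.expected = {}
            continue
        plen = len(pep.seq)
        if tier in HMM_TIER_MODEL:
            library, isotype = HMM_TIER_MODEL[tier]
            model_id = (f"TIGR{10000 + i:05d}" if library == "TIGRFAM" else f"PF{10000 + i:05d}")
            iso_field = "" if isotype == "uncharacterized" else isotype
            meta_lines.append(
                "\t".join(
                    [
                        model_id, library, iso_field, "25.0", g.name, g.symbol,
                        g.ec, " // ".join(g.go), str(g.role_id),
                    ]
                )
            )
            hmm_lines.append("\t".join([pep.id, model_id, "150.0", "1e-30"]))
        elif tier in BLAST_TIER_PARAMS:
            ident, cov = BLAST_TIER_PARAMS[tier]
            q_end = max(1, math.ceil(plen * cov / 100))
            subject = f"RF|SYN{10000 + i}.1|{700000 + i}|NC {9000 + i}"
            aln = q_end
            blast_lines.append(
                "\t".join(
                    [
                        pep.id, subject, f"{ident:.2f}", str(aln), "5", "0",
                        "1", str(q_end), "1", str(aln), "1e-50", "500.0",
                    ]
                )
            )
            curated_lines.append("\t".join([subject, g.symbol, g.name, " // ".join(g.go)]))
        elif tier == 6:
            profile = f"pd{10000 + i}"
            priam_lines.append(
                "\t".join(
                    [pep.id, profile, "95.00", str(plen), "2", "0", "1", str(plen),
                     "1", str(plen), "1e-20", "300.0"]
                )
            )
            priam_ec_lines.append(f"{profile}\t{g.ec}")
        elif tier == 23:
            tmhmm_lines.append(
                f"{pep.id}\tlen={plen}\tExpAA=66.10\tFirst60=10.20\tPredHel=4\t"
                f"Topology=i10-32o52-74i90-112o130-152i"
            )
        # tier 25: no evidence at all

    files.blast.write_text("".join(l + "\n" for l in blast_lines))
    files.curated.write_text("".join(l + "\n" for l in curated_lines))
    files.hmm.write_text("".join(l + "\n" for l in hmm_lines))
    files.model_meta.write_text("".join(l + "\n" for l in meta_lines))
    files.priam.write_text("".join(l + "\n" for l in priam_lines))
    files.priam_ec.write_text("".join(l + "\n" for l in priam_ec_lines))
    files.tmhmm.write_text("".join(l + "\n" for l in tmhmm_lines))
    return files


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    """Truth TSV: one row per planted gene, then one per ncRNA."""
    with open(path, "w") as fh:
        fh.write(
            "#kind\tid\tgenome\tstart\tend\tstrand\ttier\tname\tsymbol\tec\tgo\trole\n"
        )
        for g in truth.genes:
            fh.write(
                "\t".join(
                    [
                        "gene", g.gene_id, g.genome_id, str(g.interval.start + 1),
                        str(g.interval.end), g.strand, str(g.tier or ""), g.name,
                        g.symbol, g.ec, " // ".join(g.go), str(g.role_id),
                    ]
                )
                + "\n"
            )
        for n in truth.ncrnas:
            fh.write(
                "\t".join(
                    [
                        "ncrna", n.ncrna_id, n.genome_id, str(n.interval.start + 1),
                        str(n.interval.end), n.strand, "", n.kind, "", "", "", "",
                    ]
                )
                + "\n"
            )
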