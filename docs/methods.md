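# Methods

## Problem and approach

Shotgun metagenomic sequence from prokaryotic communities is dominated by
gene *fragments*: reads and short contigs that begin or end inside coding
regions.  `metannot` annotates such data in two stages — structural
(identify candidate proteins, full-length or truncated) and functional
(assign the best conservatively supported attributes from homology
evidence) — designed so each stage can also run alone.

## Structural annotation

### ncRNA soft-masking

tRNA loci (from tRNAscan-SE tabular output) and rRNA loci (from two
nucleotide BLAST stages against an rRNA reference, with E-value ceilings
0.1 and 1e-4) are lowercased in place.  Soft-masking preserves length and
coordinates while signalling exclusion downstream; the masked loci are also
emitted as their own FASTA records (reverse-complemented for minus-strand
loci).  Hits from all sources are unioned into a single mask — the two
BLAST stages are not intersected, since each stage is tuned to catch loci
the other misses.

### ORF model

For each strand and frame, every maximal stop-free codon run is a
candidate ORF.  Sequence edges act as virtual stop/start sites, so a run
truncated by the read boundary is kept and flagged (`truncated_5p` /
`truncated_3p` in reading orientation).  Conventions:

* The ORF interval covers the coding run only; the terminal stop codon is
  **excluded**, so the minimum-length filter applies to coding sequence.
  A 177-nt stop-bounded run fails the 180-nt minimum even though its
  stop-inclusive extent is 180 nt.
* A 3'-runoff span extends to the sequence end including the trailing
  partial codon (which is never translated); a 5' span starts at the frame
  offset.  On a 300-nt stop-free sequence the six frames therefore span
  300/299/298 nt per strand.
* No start codon is required by default: requiring ATG would discard every
  5'-truncated fragment, defeating fragment sensitivity.
  `require_start_codon=True` restores the requirement for internal
  (non-edge) runs.
* Codons containing any non-ACGT character translate to 'X', never to a
  stop, so ambiguity runs cannot split an ORF.  Translation is
  case-insensitive: masking never alters a peptide.

Filters, at defaults: span ≥ 180 nt (≈20% of the ~900 bp typical bacterial
gene); overlap with masked space ≤ 30 nt; unmasked span ≥ 150 nt.  The
masked-overlap cap is inclusive (a 180-nt ORF with exactly 150 unmasked
nucleotides passes) and absolute per ORF — it is not scaled up for longer
ORFs, keeping the rule conservative.  All three are configurable
(`StructuralConfig`), as is the codon table (NCBI translation table 11 by
default; any NCBI table id is accepted).

Clear-range mode restricts each record to the high-quality region named by
a `/clear_range=<a>-<b>` token (1-based inclusive) in its FASTA header
before analysis; the extraction offset is recorded so original coordinates
remain recoverable.  Internally all coordinates are 0-based half-open on
the forward strand; emitted tables are 1-based inclusive.

### Tagging

Ab-initio gene predictions arrive as a canonical TSV (seq_id, start, end,
strand, score, predictor); native predictor formats are versioned and are
expected to be converted by the caller.  An ORF is tagged when a
same-sequence, same-strand prediction overlaps it by ≥ 1 nt (configurable;
frame agreement is deliberately not required, since naive ORFs and
predictions can disagree by a codon at edges).  The tag source is the
prediction with the largest overlap, ties broken by higher score then
smaller start.  Tagging never alters coordinates, and untagged ORFs are
retained (emission can be restricted with `tagged_only`).

## Functional annotation

### Evidence collection

* **BLASTP** (tabular `-m 8`): hits above E = 1e-5 dropped; per query the
  10 most significant alignments kept (E ascending, bit score descending).
  Each hit is graded on the identity × coverage plane: High Confidence
  (id ≥ 35, cov ≥ 85), Conserved Domain (id ≥ 35, cov < 85), Putative
  (id < 35, cov ≥ 80), Low Confidence (otherwise).  Coverage is the
  aligned fraction of the **query** peptide: queries are fragments and the
  classes grade fragment support.  The conserved-domain class absorbs the
  id ≥ 35, 80 ≤ cov < 85 corner so the four classes partition the plane.
* **HMM hits** (canonical 4-column TSV: query, model, bit score, E-value):
  kept when score ≥ the model's trusted cutoff (inclusive, conventional
  trusted-cutoff semantics).  Model metadata (library, isotype, cutoff,
  name, symbol, EC, GO, role) travels in a sidecar TSV; hits against
  models missing from it are dropped with a warning.
* **PRIAM** (RPS-BLAST `-m 8` plus a profile→EC sidecar): E ≤ 1e-10.
* **TMHMM** short format: predicted helix count and expected membrane
  residues.
* **Lipoprotein motif**: the lipobox `[LIVMFWSTAG][LIVMFYSTAGCQ][AGS]C`
  (hydrophobic, small/hydrophobic, A/G/S, invariant lipidated cysteine)
  searched within the first 35 residues — the prokaryotic signal-peptide
  region.  Pattern and window are configurable.

### The value hierarchy

Every rankable evidence item maps to one of 25 ranks via its (type, class)
pair; Low-Confidence BLAST hits and TMHMM results below 1 predicted helix
(threshold configurable) have no rank and never annotate.  "TIGRfam
Domain" appears at ranks 5 and 18 in the curated table — a known
inconsistency, kept verbatim; the resolver gives each item the best
(smallest) rank its class appears at.  Within a rank, order is E-value
ascending, then score descending, then accession — fixed for
reproducibility.  A rank-25 DEFAULT sentinel is always appended, making
annotation total: `annotate` cannot fail on any syntactically valid
bundle.

Attribute paths beyond the common name:

* **Gene symbol** — if the hierarchy head is an HMM hit whose model
  carries a symbol, that symbol wins; otherwise the best curated-database
  BLAST subject with a symbol among the stored top-10 hits.
* **EC** — best trusted TIGRFAM model with an EC, else best PRIAM profile,
  else best Pfam model.  Conflicting ECs at one level resolve to the best
  scoring hit, with a logged warning.
* **GO** — first non-empty source of: TIGRFAM model terms; terms implied
  by the *assigned* EC (whatever its source) through the EC→GO table; Pfam
  model terms; the best curated BLAST subject's terms.  Deduplicated,
  order preserved, evidence string repeated per term.
* **Role category** — TIGRFAM models before Pfam models; role ids are
  opaque integers from the metadata table.

PRIAM can head the ranked list (rank 6) but is not name-eligible; the
common name then falls through to the next eligible item or to
"hypothetical protein".

### Output

The annotated multi-FASTA header carries 17 tab-delimited fields — user
id, peptide id, then five sections each opened by a literal marker
(`common_name`, `gene_symbol`, `GO`, `EC`, `TIGR_role`) and holding value
and evidence fields.  Multi-values join with `" // "`; empty attributes
keep their empty fields so the format stays positional and parseable.  The
summary TSV repeats the same columns with a header row (UTF-8, LF).  The
run report counts peptides per head rank.

## Synthetic data

The generator emulates the *structure* of the problem, not its full
biology.  Genomes are uniform-random nucleotide sequence (GC 50%) in which
gene cassettes and ncRNA blocks are laid out with random intergenic
spacers (minimum 25 nt).  Genes are in-frame, internally stop-free, ATG-
started, stop-terminated, sampled around the ~900 nt typical gene length
(σ = mean/4, floor 180 nt) on random strands; an in-frame stop guard
immediately upstream makes the naive ORF finder recover exactly the
planted coding span.  The first 35 codons avoid cysteine so no planted
gene spuriously matches the lipobox window.  Reads are uniformly placed,
randomly stranded substrings.  All outputs are byte-deterministic under a
fixed seed.

Mock evidence realizes a chosen hierarchy tier per gene, cycling a tier
plan across the truth table: HMM tiers write a model-metadata row carrying
the planted attributes plus a hit above cutoff; BLAST tiers write a
tabular row at the identity/coverage of the intended class plus a curated-
subject row; tier 6 writes a PRIAM hit (expected name: "hypothetical
protein", planted EC recovered); tier 23 a TMHMM line; tier 25 nothing.
Tier 24 is sequence-intrinsic (the motif lives in the peptide) and is not
realizable by an evidence file; requesting it raises.

What passing closed-loop tests shows — and does not: the pipeline's
bookkeeping (coordinates, strand handling, parsing, ranking, precedence)
is exact, since recovery is 100% by construction.  It says nothing about
sensitivity on real data, where homology is noisy, compositional bias is
real, and evidence tiers are not cleanly separable.

## Problem sizes and numerical choices

Test and validation runs use desk-scale inputs chosen as comfortable for
exhaustive oracles: ORF-finder equivalence against a brute-force stop
enumerator on 200 random masked sequences of 1–3 kb; hierarchy dominance
exhaustively over all 793 bundles of ≤ 4 items from a 12-item catalogue;
closed-loop recovery over 50 planted genes across tiers {1, 6, 12, 17, 21,
25}; classifier totality over the full 101 × 101 identity × coverage grid.
Threshold measurements in `scripts/acceptance.py` use sweeps (length
150–210 nt step 3; mask depth 0–60 nt; integer identity/coverage 1–100;
E-value decades) so each pin is observed as a transition, not read from a
constant.

Ties and degenerate inputs: empty FASTA files produce empty outputs
(exit 0); evidence keyed to unknown peptides warns rather than errors
(partial evidence is normal in metagenomic runs); malformed files error
with line numbers; duplicate TMHMM records keep the last and warn.

## Known limitations

* Native ab-initio predictor output and HMMER per-domain tables need
  external conversion to the canonical TSVs.
* No GO-DAG reasoning: terms are transferred verbatim, without ancestor
  closure or validation against an ontology release.
* The read simulator plants no sequencing errors or chimeras, and genome
  composition is uniform — fine for logic validation, unsuitable for
  benchmarking sensitivity.
* Fragment-specific HMM models and BLAST-XML export for downstream
  phylogenetic browsing are out of scope.
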