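# metannot

Fragment-aware annotation of prokaryotic shotgun metagenomic sequence:
structural annotation (gene finding on reads and assemblies) and
hierarchical functional annotation (name, gene symbol, GO terms, EC number,
functional role category) as two independently runnable components.

## Who this is for

Shotgun metagenomic reads mostly contain *fragments* of genes, so gene
callers built for complete genomes discard much of the signal.  `metannot`
implements a conservative annotation strategy for exactly this situation:

**Structural component.** Non-coding RNAs (tRNA scanner output plus two
increasingly stringent rRNA BLAST stages, E ≤ 0.1 and E ≤ 1e-4) are
soft-masked — lowercased, never removed — and written to their own FASTA
files.  A naive 6-frame scan then reports every maximal stop-free codon run
of ≥ 180 nt (≈20% of a typical ~900 bp bacterial gene), treating read edges
as virtual start/stop sites so truncated fragments are kept and flagged.
ORFs may overlap masked ncRNA space by at most 30 nt and must keep ≥ 150
unmasked nt.  Ab-initio gene predictions "tag" the ORFs they overlap;
tagged ORFs are the most probable proteins even where they extend past the
prediction boundary.

**Functional component.** For each peptide, parsed homology evidence —
BLASTP hits (E ≤ 1e-5, top 10 per query) graded into High Confidence
(identity ≥ 35%, query coverage ≥ 85%), Putative, Conserved Domain and Low
Confidence; TIGRFAM/Pfam HMM hits above per-model trusted cutoffs, classed
by isotype (equivalog … superfamily); PRIAM enzyme profiles (E ≤ 1e-10);
TMHMM helices; a lipobox regular-expression scan — is resolved through a
25-rank value hierarchy (rank 1: TIGRfam equivalog; rank 17: high-confidence
BLASTP; rank 25: hypothetical).  The head of the ranked list names the
protein; gene symbols come from curated-database BLAST hits, EC numbers
from TIGRFAM > PRIAM > Pfam, GO terms from TIGRFAM > EC mapping > Pfam >
curated BLAST, and role categories from TIGRFAM > Pfam.  PRIAM evidence
assigns EC numbers only, never a name.  Peptides without evidence are
"hypothetical protein".

No third-party search tools are executed: the package parses their standard
output formats (BLAST tabular `-m 8`, tRNAscan-SE tables, HMM hit tables,
PRIAM RPS-BLAST tabular, TMHMM short format).  A synthetic-data module
generates genomes, reads and mock evidence with planted truth, so the whole
pipeline is testable offline.

## Worked example

Generate a synthetic dataset (2 genomes, 20 planted genes cycling evidence
tiers 1, 6, 12, 17, 21, 25; 2 planted ncRNAs) and run both components:

```bash
metannot synth --out-dir demo --seed 4
metannot all --input demo/genomes.fasta --out-dir out \
  --gene-calls demo/gene_calls.tsv \
  --trnascan demo/trnascan.txt --rrna-blast-stage2 demo/rrna_blast_stage2.m8 \
  --blast demo/blast.m8 --curated-map demo/curated_subjects.tsv \
  --hmm demo/hmm_hits.tsv --model-meta demo/model_meta.tsv \
  --priam demo/priam.m8 --priam-ec demo/priam_profile_ec.tsv \
  --tmhmm demo/tmhmm.txt
```

which logs

```
INFO metannot: structural: 2 records, 2 ncRNAs masked, 123 ORFs (50 tagged), 123 peptides
INFO metannot: functional: 123 peptides annotated, 102 hypothetical
```

and writes `out/report.txt`:

```
peptides annotated	123
hypothetical	98
rank 1	HMM	TIGRfam Equivalog	4
rank 6	PRIAM	PRIAM	4
rank 12	HMM	Pfam Subfamily	3
rank 17	BLAST	Panda BLASTP High Confidence	3
rank 21	BLAST	Panda BLASTP Putative	3
rank 24	LIPOPROTEIN	Lipoprotein Motif	8
rank 25	DEFAULT	Hypothetical	98
```

All 20 planted genes are recovered at the tier their mock evidence
realizes (the 4+4+3+3+3 named ranks plus 3 evidence-free genes inside the
98 hypotheticals); the 103 remaining peptides are incidental stop-free runs
from intergenic sequence, annotated hypothetical or, where their N-terminus
happens to carry a lipobox, "putative lipoprotein" (rank 24).  A typical
annotated-FASTA header (tab-delimited, positional):

```
>syng000_865_1536_-1	syng000_865_1536_-1	common_name	synthetic protein 0	TIGR10000	gene_symbol	synA0	TIGR10000	GO	GO:7000000 // GO:7100000	TIGR10000 // TIGR10000	EC	1.1.1.1	TIGR10000	TIGR_role	100	TIGR10000
```

`out/summary.tsv` carries the same 17 columns as a flat table, and
`out/orfs.tsv` the ORF coordinates (1-based inclusive), strand, frame,
truncation flags, masked-overlap counts and tag sources.

The same functionality is importable (`metannot.find_orfs`,
`metannot.annotate`, …); the CLI is a thin layer over the library.

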