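1	HMM	TIGRfam Equivalog
2	HMM	Pfam Equivalog
3	HMM	TIGRfam Hypothetical Equivalog
4	HMM	Pfam Hypothetical Equivalog
5	HMM	TIGRfam Domain
6	PRIAM	PRIAM
7	HMM	TIGRfam Subfamily
8	HMM	TIGRfam Superfamily
9	HMM	TIGRfam EquivalogDomain
10	HMM	TIGRfam Hypothetical Equivalog Domain
11	HMM	TIGRfam Subfamily Domain
12	HMM	Pfam Subfamily
13	HMM	Pfam Superfamily
14	HMM	Pfam Equivalog Domain
15	HMM	Pfam Hypothetical Equivalog Domain
16	HMM	Pfam Subfamily Domain
17	BLAST	Panda BLASTP High Confidence
18	HMM	TIGRfam Domain
19	HMM	Pfam Domain
20	HMM	Pfam Uncharacterized
21	BLAST	Panda BLASTP Putative
22	BLAST	Panda BLASTP Conserved Domain
23	TMHMM	TMHMM
24	LIPOPROTEIN	Lipoprotein Motif
25	DEFAULT	Hypothetical
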