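##fileformat=VCFv4.2
##source=dnsnvkit consensus DNSNV fixture (22 candidates called by all three reference pipelines on the GIAB AJ trio exomes; genotypes are the canonical de novo pattern, depths unknown)
##contig=<ID=2>
##contig=<ID=3>
##contig=<ID=5>
##contig=<ID=6>
##contig=<ID=8>
##contig=<ID=9>
##contig=<ID=11>
##contig=<ID=14>
##contig=<ID=15>
##contig=<ID=17>
##contig=<ID=19>
##contig=<ID=22>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol (opaque metadata, underscores encode spaces)">
##INFO=<ID=PHENO,Number=1,Type=String,Description="Associated phenotype(s) (opaque metadata, underscores encode spaces, | separates entries)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	FATHER	MOTHER	CHILD
2	25457155	.	C	T	.	.	GENE=DTNB;PHENO=Muscular_dystrophy	GT	0/0	0/0	0/1
2	197791183	.	C	T	.	.	.	GT	0/0	0/0	0/1
2	241835203	.	G	T	.	.	.	GT	0/0	0/0	0/1
3	4669342	.	A	T	.	.	GENE=ITPR1;PHENO=Gillespie_syndrome|Spinocerebellar_ataxia_15|Spinocerebellar_ataxia_29_congenital_non-progressive	GT	0/0	0/0	0/1
3	48603870	.	G	A	.	.	GENE=UQCRC1;PHENO=Predisposition_of_Alzheimer's_disease	GT	0/0	0/0	0/1
3	52547912	.	C	G	.	.	GENE=PBRM1;PHENO=Clear_cell_renal_cell_carcinoma	GT	0/0	0/0	0/1
6	109740508	.	T	C	.	.	GENE=FIG4;PHENO=Polymicrogyria_bilateral_temporooccipital|Amyotrophic_lateral_sclerosis_11|Charcot-Marie-Tooth_disease_type_4J|Yunis-Varon_syndrome	GT	0/0	0/0	0/1
5	140730969	.	A	G	.	.	.	GT	0/0	0/0	0/1
8	30703949	.	C	G	.	.	GENE=GSR;PHENO=Hemolytic_anemia_due_to_glutathione_reductase_deficiency	GT	0/0	0/0	0/1
9	131041047	.	G	T	.	.	GENE=LAMC3;PHENO=Cortical_malformations_occipital	GT	0/0	0/0	0/1
9	131851319	.	C	G	.	.	.	GT	0/0	0/0	0/1
11	82698724	.	T	C	.	.	.	GT	0/0	0/0	0/1
14	77245340	.	C	T	.	.	GENE=TMEM63C	GT	0/0	0/0	0/1
14	93170535	.	G	A	.	.	.	GT	0/0	0/0	0/1
14	96180196	.	C	G	.	.	.	GT	0/0	0/0	0/1
14	106330036	.	T	A	.	.	.	GT	0/0	0/0	0/1
14	106993919	.	A	G	.	.	.	GT	0/0	0/0	0/1
15	79852462	.	G	T	.	.	GENE=MTHFS;PHENO=Heart_defects|lung_cancer	GT	0/0	0/0	0/1
17	53638886	.	G	A	.	.	.	GT	0/0	0/0	0/1
19	45720935	.	C	T	.	.	GENE=FBXO46	GT	0/0	0/0	0/1
22	23029544	.	A	C	.	.	.	GT	0/0	0/0	0/1
22	23029596	.	A	T	.	.	.	GT	0/0	0/0	0/1
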