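gene_id	symbol	chrom	start	end	strand	biotype	is_tf
ENSG00000062725	APPBP2	chr17	58522552	58603629	-	protein_coding	False
ENSG00000284190	MIR21	chr17	57918627	57918698	+	miRNA	False
ENSG00000170836	PPM1D	chr17	58677544	58743585	+	protein_coding	False
ENSG00000141376	BCAS3	chr17	58755560	59470199	+	protein_coding	False
ENSG00000121068	TBX2	chr17	59477257	59486827	+	protein_coding	True
ENSG00000267280	TBX2-AS1	chr17	59486937	59492000	-	lncRNA	False
ENSG00000265666	C17orf82	chr17	59492394	59494652	+	protein_coding	False
ENSG00000121075	TBX4	chr17	59533806	59562471	+	protein_coding	True
ENSG00000253506	NACA2	chr17	59668233	59669889	-	protein_coding	False
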