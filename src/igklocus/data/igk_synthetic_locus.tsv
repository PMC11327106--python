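#contig	start	end	name	feature	strand	region	class	attrs
igk_synth	0	50000	proximal	region	+	proximal	.	.
igk_synth	52000	104000	distal	region	+	distal	.	.
igk_synth	62000	65000	conversion	conversion_window	+	distal	.	.
igk_synth	92000	94000	IGKV1-NL1_ins	sv	+	distal	.	kind=insertion;payload_length=2000;carried_genes=IGKV1-NL1
igk_synth	45344	99344	INV_27	sv	+	distal	.	kind=inversion;payload_length=54000;carried_genes=
igk_synth	10200	10260	IGKV1-12	L-Part1	+	proximal	functional	gene_type=V;paralog=IGKV1D-12
igk_synth	10260	10560	IGKV1-12	intron	+	proximal	functional	gene_type=V
igk_synth	10560	10860	IGKV1-12	V-exon	+	proximal	functional	gene_type=V
igk_synth	10860	10888	IGKV1-12	RSS	+	proximal	functional	gene_type=V
igk_synth	11800	11860	IGKV1-13	L-Part1	+	proximal	functional	gene_type=V;paralog=IGKV1D-13
igk_synth	11860	12160	IGKV1-13	intron	+	proximal	functional	gene_type=V
igk_synth	12160	12460	IGKV1-13	V-exon	+	proximal	functional	gene_type=V
igk_synth	12460	12488	IGKV1-13	RSS	+	proximal	functional	gene_type=V
igk_synth	25000	25060	IGKV3-20	L-Part1	+	proximal	functional	gene_type=V;paralog=IGKV3D-20
igk_synth	25060	25360	IGKV3-20	intron	+	proximal	functional	gene_type=V
igk_synth	25360	25660	IGKV3-20	V-exon	+	proximal	functional	gene_type=V
igk_synth	25660	25688	IGKV3-20	RSS	+	proximal	functional	gene_type=V
igk_synth	45000	45060	IGKV1-27	L-Part1	+	proximal	functional	gene_type=V;paralog=IGKV1D-27
igk_synth	45060	45360	IGKV1-27	intron	+	proximal	functional	gene_type=V
igk_synth	45360	45660	IGKV1-27	V-exon	+	proximal	functional	gene_type=V
igk_synth	45660	45688	IGKV1-27	RSS	+	proximal	functional	gene_type=V
igk_synth	47000	47039	IGKJ1	J-exon	+	proximal	functional	gene_type=J
igk_synth	47050	47078	IGKJ1	RSS	+	proximal	functional	gene_type=J
igk_synth	48000	48321	IGKC	C-exon	+	proximal	functional	gene_type=C
igk_synth	62200	62260	IGKV1D-12	L-Part1	+	distal	functional	gene_type=V;paralog=IGKV1-12
igk_synth	62260	62560	IGKV1D-12	intron	+	distal	functional	gene_type=V
igk_synth	62560	62860	IGKV1D-12	V-exon	+	distal	functional	gene_type=V
igk_synth	62860	62888	IGKV1D-12	RSS	+	distal	functional	gene_type=V
igk_synth	63800	63860	IGKV1D-13	L-Part1	+	distal	functional	gene_type=V;paralog=IGKV1-13
igk_synth	63860	64160	IGKV1D-13	intron	+	distal	functional	gene_type=V
igk_synth	64160	64460	IGKV1D-13	V-exon	+	distal	functional	gene_type=V
igk_synth	64460	64488	IGKV1D-13	RSS	+	distal	functional	gene_type=V
igk_synth	77000	77060	IGKV3D-20	L-Part1	+	distal	functional	gene_type=V;paralog=IGKV3-20
igk_synth	77060	77360	IGKV3D-20	intron	+	distal	functional	gene_type=V
igk_synth	77360	77660	IGKV3D-20	V-exon	+	distal	functional	gene_type=V
igk_synth	77660	77688	IGKV3D-20	RSS	+	distal	functional	gene_type=V
igk_synth	82000	82060	IGKV2D-40	L-Part1	-	distal	functional	gene_type=V
igk_synth	82060	82360	IGKV2D-40	intron	-	distal	functional	gene_type=V
igk_synth	82360	82660	IGKV2D-40	V-exon	-	distal	functional	gene_type=V
igk_synth	82660	82688	IGKV2D-40	RSS	-	distal	functional	gene_type=V
igk_synth	92600	92660	IGKV1-NL1	L-Part1	+	distal	functional	gene_type=V
igk_synth	92660	92960	IGKV1-NL1	intron	+	distal	functional	gene_type=V
igk_synth	92960	93260	IGKV1-NL1	V-exon	+	distal	functional	gene_type=V
igk_synth	93260	93288	IGKV1-NL1	RSS	+	distal	functional	gene_type=V
igk_synth	99000	99060	IGKV1D-27	L-Part1	+	distal	functional	gene_type=V;paralog=IGKV1-27
igk_synth	99060	99360	IGKV1D-27	intron	+	distal	functional	gene_type=V
igk_synth	99360	99660	IGKV1D-27	V-exon	+	distal	functional	gene_type=V
igk_synth	99660	99688	IGKV1D-27	RSS	+	distal	functional	gene_type=V
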