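gene_id	rnaseq_screen	panel_reference	public_study_1	public_study_2	public_study_3	meta_analysis
Atp5h	X	X	X	X	X	X
Gsk3b	X	X	X	X	X	X
Sirt2	X	X	X	X	X	X
Nono	-	X	ND	X	X	X
Tprkb	X	X	X	X	X	-
Tspo	X	X	X	X	X	-
Ttr	X	-	X	X	X	X
Gr	-	X	ND	X	X	-
H3f3a	X	X	-	-	X	X
Pqbp1	X	-	ND	X	X	-
Rora	X	X	ND	X	-	-
S100a1	X	X	-	X	X	-
Aox3	X	-	X	X	-	-
H3f3b	-	-	X	X	X	-
Tomm7	X	X	-	X	-	-
Gapdh	X	-	-	X	-	-
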