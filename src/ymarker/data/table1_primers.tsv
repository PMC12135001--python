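primer_id	type	gene_id	forward_seq	reverse_seq	xy_ds	amplicon_bp
23	XY	PK05076.1	GTTATATGGACATGGACTCT	TTTTTCTGATAGTGCGCC	0.225	174
36	XY	PK18889.1	AAAAGGGGTGAAAAGGTG	CCTCTCTTTCTTGATGAACT	0.187	300
9	autosomal	PK01688.1	GTTTCATCGGTTGCTTTCT	TCCCTATTCTCATCCCTCT	NA	514
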