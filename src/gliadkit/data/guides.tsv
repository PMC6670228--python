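name	protospacer	targets_antisense	region_class	anchor_column	family
sgRNA_alpha87	GATTTTGTGGCTGCAATTG	true	post_signal_peptide	87	alpha
sgRNA_alpha213	ATGGTTGTTGTGATGGAAA	true	epitope_upstream	213	alpha
sgRNA_alpha324	GTTGTGGTCGAAATGGTTG	true	epitope_downstream	324	alpha
sgRNA_gamma86	TTGTTGTGGCCATTGTACT	true	post_signal_peptide	86	gamma
sgRNA_gamma272	AATGGTTGTTGTGGTTGCTG	true	epitope_internal	274	gamma
sgRNA_gamma603	TGCTGGGGGAATGATTGTTG	true	epitope_downstream	603	gamma
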