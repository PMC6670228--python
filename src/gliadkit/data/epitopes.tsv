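name	peptide	families
# Canonical CD epitope 9-mer cores, stored in genomically encoded Q-form
# (deamidated registry forms substitute E at tTG-targeted positions; scan
# with qe_equivalence=True to match those). Editable input data.
DQ2.5-glia-a1a	PFPQPQLPY	alpha
DQ2.5-glia-a1b	PYPQPQLPY	alpha
DQ2.5-glia-a2	PQPQLPYPQ	alpha
DQ2.5-glia-a3	FRPQQPYPQ	alpha
DQ8-glia-a1	QGSFQPSQQ	alpha
DQ2.5-glia-g1	PQQSFPQQQ	gamma
DQ2.5-glia-g2	IQPQQPAQL	gamma
DQ2.5-glia-g3	QQPQQPYPQ	gamma
DQ2.5-glia-g4a	SQPQQQFPQ	gamma
DQ2.5-glia-g4b	PQPQQQFPQ	gamma
DQ2.5-glia-g4c	QQPQQPFPQ	gamma
DQ2.5-glia-g4d	PQPQQPFCQ	gamma
DQ2.5-glia-g5	QQPFPQQPQ	gamma
DQ2.5-glia-w1	PFPQPQQPF	omega
DQ2.5-glia-w2	PQPQQPFPW	omega
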