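motif_id	sequence	epitope_class	source	min_core_match
R5-QQPFP	QQPFP	R5	Osman et al. 2001; R5 mAb recognition motif	5
R5-QQQFP	QQQFP	R5	Osman et al. 2001; R5 mAb recognition motif	5
R5-QLPFP	QLPFP	R5	Osman et al. 2001; R5 mAb recognition motif	5
R5-LQPFP	LQPFP	R5	Osman et al. 2001; R5 mAb recognition motif	5
DQ2.5-glia-a1a	PFPQPQLPY	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-glia-a1b	PYPQPQLPY	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-glia-a2	PQPQLPYPQ	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-glia-a3	FRPQQPYPQ	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-glia-g1	PQQSFPQQQ	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-glia-g2	IQPQQPAQL	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-glia-g3	QQPQQPYPQ	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-glia-g4a	SQPQQQFPQ	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-glia-g4c	QQPQQPFPQ	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-glia-w1	PFPQPQQPF	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-glia-w2	PQPQQPFPW	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-hor-2	PQPQQPFPQ	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ2.5-hor-3	PIPQQPQPY	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
DQ8-glia-a1	QGSFQPSQQ	DQ_core	Sollid et al. 2012/2020 nomenclature; curated	9
IEDB-226653	PQQPFPQPQQPFP	immunogenic_Tcell	IEDB epitope ID 226653; curated	9
Tcell-hor-R15rel	IIPQQPQQPFPQQPQQ	immunogenic_Tcell	C-hordein repeat region related to rye secalin peptide R15 (Tye-Din et al. 2010); curated	9
Tcell-hor-B29rel	SQQPQQPFPQQPQQPF	immunogenic_Tcell	C-hordein repeat region related to barley peptide B29 (Tye-Din et al. 2010); curated	9
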