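# Human mitochondrial gene table, BED6, 0-based half-open, chrM length 16569.
# Coordinates follow the revised Cambridge reference sequence, with the ATP6,
# COX3 and ND4 starts nudged past their upstream neighbours so that intervals
# within the partition are non-overlapping (the real ATP8/ATP6 and ND4L/ND4
# reading frames overlap by a few dozen bases).  DLOOP is the non-coding
# control region; it wraps the origin of the circular genome and is stored as
# two arcs sharing one name.  Strand column: + = heavy, - = light.
chrM	16023	16569	DLOOP	0	+
chrM	0	576	DLOOP	0	+
chrM	647	1601	RNR1	0	+
chrM	1670	3229	RNR2	0	+
chrM	3306	4262	ND1	0	+
chrM	4469	5511	ND2	0	+
chrM	5903	7445	COX1	0	+
chrM	7585	8269	COX2	0	+
chrM	8365	8572	ATP8	0	+
chrM	8572	9207	ATP6	0	+
chrM	9207	9990	COX3	0	+
chrM	10058	10404	ND3	0	+
chrM	10469	10766	ND4L	0	+
chrM	10766	12137	ND4	0	+
chrM	12336	14148	ND5	0	+
chrM	14148	14673	ND6	0	-
chrM	14746	15887	CYTB	0	+
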