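# name	pattern	description
GT1	GAAAAA	GT-1 motif; pathogen- and salt-induced expression
WBOX	TTGAC	W box; bound by salicylic-acid-induced WRKY proteins
ASF1	TGACG	ASF-1 binding site; auxin/salicylic-acid activation
LTRE1	CCGAAA	Low-temperature responsive element
LTRE2	ACCGACA	Low-temperature responsive element
LTRE3	CCGAC	Low-temperature responsive element core
ARF	TGTCTC	Auxin response factor binding site
AUXRE	KGTCCCAT	Auxin response element
DREB	TACCGACAT	DREB binding site; drought/cold/salt responsiveness
TCA1	TCATCTTCTT	TCA-1 motif; salicylic-acid-mediated expression
ABRE	ACGTG	ABA-responsive element core
GCC	GCCGCC	GCC box core; jasmonic-acid-induced expression
TGBOX	AACGTG	T/G-box; jasmonate induction via MYC factors
DOF	AAAG	Dof protein core binding site
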