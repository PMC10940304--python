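motif_id	consensus	stimulus
ABRE	ACGTG	Abscisic acid
AuxRR-core	GGTCCAT	Auxin
TGA-element	AACGAC	Auxin
CGTCA-motif	CGTCA	MeJA
TGACG-motif	TGACG	MeJA
GARE-motif	TCTGTTG	Gibberellin
P-box	CCTTTTG	Gibberellin
TATC-box	TATCCCA	Gibberellin
TCA-element	CCATCTTTTT	Salicylic acid
SARE	TTCGACCATCTT	Salicylic acid
DRE	RCCGAC	Dehydration
MBS	CAACTG	Drought
LTR	CCGAAA	Low-temperature
TC-rich_repeats	ATTTTCTTCA	Defense and stress
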