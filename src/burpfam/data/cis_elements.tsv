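# Starter cis-element table with literature consensus patterns.
# These are NON-CANONICAL stand-ins for database position matrices: plain
# IUPAC consensus strings chosen for scanning demonstrations and tests.
name	pattern	category
TCA-element	CCATCTTTTT	hormone
TGA-element	AACGAC	hormone
GARE-motif	TCTGTTG	hormone
ABRE	TACGTG	hormone
TGACG-motif	TGACG	hormone
ARE	AAACCA	stress
MBS	CAACTG	stress
HSE	AAAAAATTTC	stress
TC-rich	ATTTTCTTCA	stress
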