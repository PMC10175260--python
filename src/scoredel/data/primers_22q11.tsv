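gene	forward	reverse	expected_size
TBX1	CCCTTACCTACCCGAGTGGA	AAGACGCCCATTTCTCCCAG	101
HIRA	CTGGTCACCTGATGGGCATT	CCCTCCCGTTCGATGATCTG	84
COMT	AGCACAGGTGGGTTTCTACG	AGTGAGAAAATGGAGGGCGG	83
CRKL	GTATGTTCCTCGTCCGCGAT	TTGGGCAGCGAGTTGATGAT	103
BID	GGCTGTGAAGGCTATGGTGT	AGGCTGACAGTTGAGAGCTG	78
MAPK1	CTGTGACCTCTCAGATCCTCT	ATCTGGCGGTTCTACAAGAGTG	70
RPPH1	GTGAGTTCCCAGAGAACGGG	TGAGTCTGTTCCAAGCTCCG	120
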