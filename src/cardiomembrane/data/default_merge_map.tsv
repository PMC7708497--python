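from_accession	to_accession	gene_symbol
Q62351	P02786	TFRC
Q9D880	Q3ZCQ8	TIMM50
Q8R326	Q8WXF1	PSPC1
Q6R0H6	P84996	GNAS
Q61029	P42167	TMPO
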