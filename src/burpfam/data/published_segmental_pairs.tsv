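species	gene_a	gene_b	ks_mean	ks_sd	age_printed_mya
arabidopsis	AT1G70370	AT1G23760	0.795	0.122	26.5
brassica	Brara.I00536	Brara.B03626	0.480	0.203	17.1
brassica	Brara.F02754	Brara.I00536	0.451	0.123	16.1
brassica	Brara.F02754	Brara.B03626	0.441	0.191	15.8
brassica	Brara.G02440	Brara.G02959	0.380	0.074	13.6
soybean	Glyma.06G013400	Glyma.11G119100	0.553	0.102	45.3
soybean	Glyma.06G013400	Glyma.12G044600	0.548	0.163	44.9
soybean	Glyma.12G217300	Glyma.13G283900	0.145	0.083	11.9
soybean	Glyma.02G034700	Glyma.01G030900	0.151	0.051	12.3
soybean	Glyma.06G081100	Glyma.04G079600	0.132	0.042	10.8
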