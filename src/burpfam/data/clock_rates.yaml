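# Species-specific synonymous substitution rates (substitutions/site/year)
soybean: 6.1e-9
brassica: 1.4e-8
arabidopsis: 1.5e-8
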