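species	gene_a	gene_b	d4dtv
Setaria italica	Si014261m.g	Si014260m.g	0.0000
Setaria italica	Si014261m.g	Si014258m.g	0.0270
Setaria italica	Si014260m.g	Si014258m.g	0.0268
Setaria italica	Si006838m.g	Si006050m.g	1.6000
Sorghum bicolor	Sobic.008G157800	Sobic.008G157700	0.8424
Sorghum bicolor	Sobic.008G157800	Sobic.008G157500	0.4927
Sorghum bicolor	Sobic.008G157800	Sobic.008G157600	0.5364
Sorghum bicolor	Sobic.008G157700	Sobic.008G157500	0.6103
Sorghum bicolor	Sobic.008G157700	Sobic.008G157600	0.5243
Sorghum bicolor	Sobic.008G157500	Sobic.008G157600	0.1370
Citrus sinensis	Orange1.1g044596m	Orange1.1g036311m	0.6667
Glycine max	Glyma.14G140900	Glyma.14G141000	0.1259
Glycine max	Glyma.11G119100	Glyma.11G119900	0.7027
Glycine max	Glyma.12G217300	Glyma.12G217400	0.0504
Glycine max	Glyma.18G138000	Glyma.18G138200	0.2310
Populus trichocarpa	Potri.006G243600	Potri.006G243700	0.0697
Populus trichocarpa	Potri.T012700	Potri.T012500	0.0258
Populus trichocarpa	Potri.004G136900	Potri.004G136500	0.0198
Populus trichocarpa	Potri.004G136900	Potri.004G136700	0.0001
Populus trichocarpa	Potri.004G136900	Potri.004G136000	0.0380
Populus trichocarpa	Potri.004G136900	Potri.004G136600	0.0060
Populus trichocarpa	Potri.004G136500	Potri.004G136700	0.0202
Populus trichocarpa	Potri.004G136500	Potri.004G136000	0.0234
Populus trichocarpa	Potri.004G136500	Potri.004G136600	0.0225
Populus trichocarpa	Potri.004G136700	Potri.004G136000	0.0029
Populus trichocarpa	Potri.004G136700	Potri.004G136600	0.0057
Populus trichocarpa	Potri.004G136000	Potri.004G136600	0.0057
Populus trichocarpa	Potri.009G114300	Potri.009G114600	0.5909
Populus trichocarpa	Potri.010G040800	Potri.010G040900	0.0000
Cucumis sativus	Cucsa.109710	Cucsa.109700	0.9248
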