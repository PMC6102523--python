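model	n_params	lnl
M0	1	-20918.0
M3	5	-20403.3
M7	2	-20362.5
M8	4	-24885.1
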