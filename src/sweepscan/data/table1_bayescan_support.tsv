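test	contrast	chrom	start_bp	end_bp
Bayescan	EUT	7	36720000	38670000
Bayescan	EUT	8	88100000	90020000
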