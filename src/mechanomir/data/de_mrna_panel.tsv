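feature_id	feature_type	fold_change	p_value	fdr
STC1	coding	12.79	0.0002	0.0002
TMEM45A	coding	9.64	0.0002	0.0002
CA9	coding	7.75	0.0011	0.0011
ITGA3	coding	2.34	0.0245	0.0245
FOXN2	coding	-2.63	0.0386	0.0386
LY6K	coding	4.83	0.0072	0.0072
CTGF	coding	2.17	0.0314	0.0314
VEGFA	coding	3.02	0.0072	0.0072
VEGFB	coding	2.04	0.0177	0.0177
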