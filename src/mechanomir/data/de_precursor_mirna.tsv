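feature_id	feature_type	fold_change	p_value	fdr	gbm_relevant
mir-31-HG	precursor_mirna	-2.03	0.01	0.01	TRUE
mir-100-HG	precursor_mirna	-2.63	0.01	0.01	TRUE
mir-181-A1-HG	precursor_mirna	-4.2	0.01	0.01	TRUE
mir-181-B1	precursor_mirna	-2.9	0.01	0.01	TRUE
mir-421	precursor_mirna	-2.05	0.01	0.01	TRUE
mir-423	precursor_mirna	-3.28	0.01	0.01	TRUE
mir-454	precursor_mirna	-2.22	0.01	0.01	TRUE
mir-548-AJ2	precursor_mirna	-2.16	0.01	0.01	TRUE
mir-548-AZ	precursor_mirna	-2.03	0.01	0.01	TRUE
mir-548-T	precursor_mirna	-2.3	0.01	0.01	TRUE
let-7i	precursor_mirna	-3.35	0.01	0.01	TRUE
mir-563	precursor_mirna	-2.38	0.01	0.01	FALSE
mir-569	precursor_mirna	-2.55	0.01	0.01	FALSE
mir-604	precursor_mirna	-3.06	0.01	0.01	FALSE
mir-4477-B	precursor_mirna	-2.21	0.01	0.01	FALSE
mir-6125	precursor_mirna	-2.2	0.01	0.01	FALSE
mir-6839	precursor_mirna	-2.43	0.01	0.01	FALSE
mir-7978	precursor_mirna	-2.78	0.01	0.01	FALSE
mir-8063	precursor_mirna	-2.7	0.01	0.01	FALSE
mir-924	precursor_mirna	-3.32	0.01	0.01	FALSE
mir-943	precursor_mirna	2.02	0.01	0.01	FALSE
mir-3614	precursor_mirna	2.02	0.01	0.01	FALSE
mir-8085	precursor_mirna	2.06	0.01	0.01	FALSE
mir-4640	precursor_mirna	2.12	0.01	0.01	FALSE
mir-6884	precursor_mirna	2.19	0.01	0.01	FALSE
mir-3611	precursor_mirna	4.17	0.01	0.01	FALSE
mir-6787	precursor_mirna	4.95	0.01	0.01	FALSE
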