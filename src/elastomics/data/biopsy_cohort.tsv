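patient_id	sample_id	radiological_class	surgeon_eval	gstar_norm	mre_label
1	1	CE	Stiff	0.82	Soft
1	2	FLAIR	Stiff	1.88	Stiff
1	3	CE	Soft	1.27	Soft
2	1	FLAIR	Soft	0.76	Soft
2	2	CE	Soft	0.88	Stiff
2	3	CE	Soft	0.70	Soft
3	1	CE	Soft	0.67	Stiff
3	2	Necrosis	Stiff	0.54	Soft
3	3	Necrosis	Stiff	0.48	Soft
4	1	FLAIR	Soft	1.22	Stiff
4	2	CE	Soft	1.01	Stiff
4	3	Necrosis	Stiff	0.45	Soft
5	1	FLAIR	Soft	0.40	Soft
5	2	Necrosis	Soft	1.04	Stiff
5	3	CE	Stiff	0.76	Stiff
6	1	CE	Soft	0.79	Stiff
6	2	CE	Soft	0.60	Soft
6	3	CE	Stiff	0.82	Stiff
7	1	CE	Soft	0.53	Soft
7	2	CE	Soft	0.74	Stiff
8	1	CE	Stiff	1.00	Stiff
8	2	CE	Stiff	0.48	Soft
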