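exposure	mediator	outcome	ie	de	te	ie_over_te	pval
ICP	LDL	CVD	0.001	0.003	0.004	0.255	2.952E-04
ICP	TC	CVD	0.001	0.004	0.004	0.122	0.007
ICP	Apo-B	CVD	0.001	0.003	0.004	0.213	0.004
ICP	LDL	HTN	2.682E-04	0.002	0.002	0.110	0.012
ICP	TC	HTN	9.914E-05	0.002	0.002	0.040	0.210
ICP	Apo-B	HTN	2.274E-04	0.002	0.002	0.093	0.031
ICP	LDL	CAD	0.009	0.030	0.039	0.237	0.039
ICP	TC	CAD	0.004	0.035	0.039	0.100	0.300
ICP	Apo-B	CAD	0.006	0.033	0.039	0.163	0.075
ICP	HTN	CAD	0.006	0.033	0.039	0.145	0.032
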