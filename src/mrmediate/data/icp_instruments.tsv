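chrom	pos	snp_id	effect_allele	other_allele	eaf	beta	se	pval
14	94378610	rs28929474	T	C	0.020	1.958	0.176	1.041E-28
17	79732281	rs34491636	A	G	0.774	-0.308	0.052	2.620E-09
19	35552195	rs2251250	T	C	0.342	0.290	0.045	1.414E-10
19	47867143	rs296384	T	G	0.844	0.378	0.060	2.501E-10
2	169077231	rs1862069	A	G	0.555	-0.340	0.043	2.043E-15
2	27508073	rs1260326	T	C	0.369	-0.360	0.045	6.838E-16
2	43844604	rs4148211	A	G	0.574	0.529	0.044	1.722E-33
20	44413724	rs1800961	T	C	0.040	0.724	0.115	3.420E-10
4	76490987	rs13146355	A	G	0.454	0.242	0.043	1.995E-08
7	87497783	rs55747905	T	C	0.828	0.485	0.058	7.913E-17
8	58480178	rs10107182	T	C	0.636	-0.403	0.045	1.952E-19
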