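rsid	effect_allele	other_allele	eaf	beta	se
rs10455872	G	A	0.07	25.6	0.086
rs3798220	C	T	0.02	12.1	0.08
rs5602509	A	C	0.397	13.69	0.324
rs4993604	A	C	0.102	9.82	0.246
rs5884689	T	G	0.237	5.63	0.163
rs6596948	T	C	0.161	5.76	0.165
rs2311660	T	G	0.083	2.34	0.097
rs8173707	T	C	0.408	3.59	0.122
rs2331332	C	T	0.222	1.37	0.077
rs2157128	T	G	0.109	13.59	0.322
rs4613426	C	T	0.319	7.99	0.21
rs1633784	G	A	0.131	2.91	0.108
rs4320936	T	G	0.411	12.09	0.292
rs9353886	C	T	0.137	3.93	0.129
rs9815004	T	C	0.063	1.93	0.089
rs2167964	G	T	0.13	9.98	0.25
rs9534948	T	G	0.188	14.44	0.339
rs5369521	C	T	0.238	1.4	0.078
rs5929769	C	A	0.412	13.08	0.312
rs6310283	C	T	0.329	3.85	0.127
rs7789930	A	G	0.186	2.39	0.098
rs1258200	A	G	0.057	1.27	0.075
rs5493489	A	G	0.114	5.39	0.158
rs8815002	G	A	0.449	11.91	0.288
rs7409536	T	C	0.234	8.4	0.218
rs6965586	C	T	0.326	13.79	0.326
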