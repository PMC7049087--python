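rsid	effect_allele	other_allele	eaf	beta	se
rs10455872	C	A	0.07	25.6	0.318
rs3798220	T	C	0.02	12.1	0.289
rs6932541	A	C	0.426	12.71	0.304
rs8681105	T	C	0.055	6.75	0.185
rs5236296	C	A	0.381	2.66	0.103
rs4736997	G	T	0.151	7.83	0.207
rs2815560	T	C	0.3	5.97	0.169
rs2816010	G	T	0.356	6.98	0.19
rs6453887	A	C	0.389	15.89	0.368
rs7449258	G	A	0.426	5.64	0.163
rs4930590	C	T	0.304	12.74	0.305
rs7862561	T	C	0.394	3.5	0.12
rs2157795	T	G	0.249	9.91	0.248
rs1323186	A	G	0.143	6.2	0.174
rs3371815	G	T	0.114	4.64	0.143
rs4801094	T	G	0.249	6.89	0.188
rs7154524	T	G	0.348	15.01	0.35
rs6773112	G	A	0.23	9.68	0.244
rs7245383	C	A	0.323	8.77	0.225
rs6880101	T	C	0.1	13.05	0.311
rs2023370	G	A	0.439	8.56	0.221
rs1970693	C	T	0.24	2.69	0.104
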