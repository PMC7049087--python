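rsid	effect_allele	other_allele	eaf	beta	se
rs10455872	C	A	0.07	23.33	0.318
rs3798220	T	C	0.02	10.87	0.289
rs6932541	A	C	0.426	9.16	0.304
rs8681105	T	C	0.055	6.15	0.185
rs5236296	C	A	0.381	2.12	0.103
rs4736997	G	T	0.151	6.54	0.207
rs2815560	T	C	0.3	5.94	0.169
rs2816010	G	T	0.356	5.02	0.19
rs6453887	A	C	0.389	12.0	0.368
rs7449258	G	A	0.426	4.13	0.163
rs4930590	C	T	0.304	12.16	0.305
rs7862561	T	C	0.394	3.18	0.12
rs2157795	T	G	0.249	7.66	0.248
rs1323186	A	G	0.143	4.58	0.174
rs3371815	G	T	0.114	4.23	0.143
rs4801094	T	G	0.249	5.22	0.188
rs7154524	T	G	0.348	11.78	0.35
rs6773112	G	A	0.23	8.83	0.244
rs7245383	C	A	0.323	6.31	0.225
rs6880101	T	C	0.1	10.35	0.311
rs2023370	G	A	0.439	7.29	0.221
rs1970693	C	T	0.24	2.39	0.104
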