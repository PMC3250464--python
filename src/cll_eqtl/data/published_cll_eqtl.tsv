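gene	snp_id	r2_with_index	chrom	pos	snp_location	major_allele	minor_allele	raw_p	adjusted_p_published	direction	is_index
SP140	rs6716753	0.95	2	231097129	Intron 1 of SP140	T	C	5.88E-03	0.186	down	0
SP140	rs6743984	0.95	2	231109329	Intron 5 of SP140	T	C	5.88E-03	0.186	down	0
SP140	rs7423615	1	2	231116874	Intron 10 of SP140	C	T	1.87E-03	0.114	down	0
SP140	rs7563433	1	2	231095678	Intron 1 of SP140	T	C	6.10E-03	0.186	down	0
SP140	rs9989746	0.89	2	231115790	Intron 10 of SP140	G	A	6.72E-04	0.082	down	0
SP140	rs9989835	1	2	231115630	Intron 9 of SP140	A	T	4.49E-03	0.171	down	0
SP140	rs9989899	1	2	231114131	Intron 9 of SP140	G	A	1.87E-03	0.114	down	0
SP140	rs10198539	0.89	2	231105646	Intron 5 of SP140	C	T	8.43E-04	0.086	down	0
SP140	rs10201872	0.89	2	231106724	Intron 5 of SP140	C	T	6.72E-04	0.082	down	0
SP140	rs10202244	0.89	2	231106935	Intron 5 of SP140	G	T	6.72E-04	0.082	down	0
SP140	rs10209615	0.83	2	231089943	Upstream of SP140	T	C	4.66E-04	0.082	down	0
SP140	rs10498246	1	2	231116417	Intron 10 of SP140	T	A	3.09E-03	0.157	down	0
SP140	rs13384787	0.89	2	231088084	Upstream of SP140	A	C	6.72E-04	0.082	down	0
SP140	rs13385151	1	2	231115976	Intron 10 of SP140	C	T	3.75E-03	0.164	down	0
SP140	rs13397985	-	2	231091223	Intron 1 of SP140	T	G	3.09E-03	0.157	down	1
SP140	rs28445040	1	2	231110582	Exon 7 of SP140	C	T	1.87E-03	0.114	down	0
GNG8	rs4802322	0.95	19	47242992	Intron 1 of STRN4	A	G	6.63E-03	0.193	up	0
GNG8	rs11083846	-	19	47207654	Intron 5 of PRKD2	G	A	3.34E-03	0.157	up	1
DACT3	rs4802322	0.95	19	47242992	Intron 1 of STRN4	G	A	4.01E-03	0.164	up	0
DACT3	rs11083846	-	19	47207654	Intron 5 of PRKD2	G	A	1.85E-03	0.114	up	1
DACT3	rs11670473	0.88	19	47257481	Intron 3 of FKRP	G	A	5.01E-03	0.180	up	0
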