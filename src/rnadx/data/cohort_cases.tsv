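case_id	group	gene	n_splice_vus	analysis_successful	effect_present	effect_significant	protein_mechanism_possible	hi_analysis	hi_candidate_found	citation
1	splice_noncanonical	SASS6	1	true	true	true	false	false	false	Table 1 Case 1
2	splice_noncanonical	NFU1	1	true	true	true	false	false	false	Table 1 Case 2
3	splice_noncanonical	PPP1R2	1	true	true	NA	false	true	false	Table 1 Case 3
4	splice_noncanonical	NA	2	true	true	false	false	true	false	Results, splice variants (Case 4: mild effect for one of two variants, diagnosis ruled out)
5	splice_noncanonical	NA	1	true	false	NA	false	true	false	Results, splice variants (negative cases 5-7, 23, 49, 50)
6	splice_noncanonical	NA	1	true	false	NA	false	true	false	Results, splice variants (negative cases 5-7, 23, 49, 50)
7	splice_noncanonical	NA	1	true	false	NA	false	true	false	Results, splice variants (negative cases 5-7, 23, 49, 50)
8	splice_noncanonical	PIEZO1	1	true	true	true	false	false	false	Table 1 Case 8
9	splice_noncanonical	ELN	1	true	true	true	false	false	false	Table 1 Case 9
10	splice_noncanonical	FOXRED1	2	true	true	true	false	false	false	Table 1 Case 10
11	splice_noncanonical	PQBP1	1	true	true	NA	false	true	false	Table 1 Case 11
12	splice_noncanonical	PIEZO2	1	true	true	true	false	false	false	Table 1 Case 12
13	canonical_splice_atypical	EFTUD2	1	true	true	true	false	false	false	Table 1 Case 13
14	canonical_splice_atypical	TBX6	1	true	true	NA	false	true	false	Table 1 Case 14
15	canonical_splice_atypical	MED14	1	true	true	NA	false	true	false	Table 1 Case 15
16	canonical_splice_atypical	RABGAP1	1	true	true	NA	false	true	false	Table 1 Case 16
17	canonical_splice_atypical	SYNGAP1	1	true	true	true	false	false	false	Table 1 Case 17
18	splice_noncanonical	TGM1	1	true	true	true	false	false	false	Table 1 Case 18 (also intragenic CNV section)
19	intragenic_cnv	COL4A5	0	true	true	true	false	false	false	Table 1 Case 19
20	intragenic_cnv	CDKL5	0	true	true	true	false	false	false	Table 1 Case 20
21	intragenic_cnv	TONSL	0	true	true	true	false	false	false	Table 1 Case 21
22	intragenic_cnv	NA	0	false	false	NA	false	false	false	Results, CNV section (Case 22: no reads in duplication region; maternal tissue)
23	splice_noncanonical	NA	1	true	false	NA	true	false	false	Results, splice variants (missense; transcript effect ruled out)
24	regulatory_utr	IDUA	0	true	true	true	false	false	false	Table 1 Case 24
25	regulatory_utr	NA	0	true	false	NA	false	true	false	Results, UTR section (negative cases 25-27)
26	regulatory_utr	NA	0	true	false	NA	false	true	false	Results, UTR section (negative cases 25-27)
27	regulatory_utr	NA	0	true	false	NA	false	true	false	Results, UTR section (negative cases 25-27)
28	regulatory_utr	MAMLD1	0	true	true	NA	false	true	false	Table 1 Case 28
29	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
30	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
31	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
32	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
33	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
34	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
35	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (Case 35: sibling muscle biopsy)
36	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
37	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
38	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
39	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
40	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
41	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
42	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
43	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
44	wgs_negative	HUWE1	0	true	false	NA	false	true	true	Table 1 Case 44 (single hypothesis-independent candidate)
45	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
46	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
47	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
48	wgs_negative	NA	0	true	false	NA	false	true	false	Results, WGS-negative section (20 probands)
49	splice_noncanonical	NA	1	true	false	NA	false	true	false	Results, splice variants (negative cases 5-7, 23, 49, 50)
50	splice_noncanonical	NA	1	true	false	NA	true	false	false	Results, splice variants (missense; transcript effect ruled out)
51	splice_noncanonical	FBXL4	1	true	true	true	false	false	false	Table 1 Case 51
52	splice_noncanonical	ACADM	1	true	true	true	false	false	false	Table 1 Case 52
53	splice_noncanonical	UFC1	1	true	true	NA	false	true	false	Table 1 Case 53
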