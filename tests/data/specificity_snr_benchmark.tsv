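target	experiment	recognized_probes	snr_nonspecific	snr_specific	p_value_specific
B. fragilis ATCC25285	1	Bacteroides/Prevotella	0.85	30.81	9.35E-05
B. fragilis ATCC25285	2	Bacteroides/Prevotella	0.53	21.45	7.39E-04
B. thetaiotaomicron ATCC29148	1	Bacteroides/Prevotella	0.45	61.44	2.56E-04
B. thetaiotaomicron ATCC29148	2	Bacteroides/Prevotella	1.66	347.24	9.10E-06
L. gasseri DSM20243	1	Lactobacillaceae	0.30	5.58	4.98E-03
L. gasseri DSM20243	2	Lactobacillaceae	1.56	20.59	6.58E-03
P. melaninogenica ATCC25845	1	Bacteroides/Prevotella	1.54	480.24	6.02E-08
P. melaninogenica ATCC25845	2	Bacteroides/Prevotella	0.90	266.63	3.74E-09
B. subtilis DSM704	1	Bacillus subtilis et rel.	7.93	637.39	1.56E-09
B. subtilis DSM704	2	Bacillus subtilis et rel.	5.62	350.10	1.47E-05
E. coli ATCC11105	1	Enterobacteriaceae	3.27	555.04	8.65E-08
E. coli ATCC11105	2	Enterobacteriaceae	2.59	222.39	4.50E-07
P. mirabilis DSM4479	1	Proteus; Enterobacteriaceae	2.42	703.22	7.74E-09
P. mirabilis DSM4479	2	Proteus; Enterobacteriaceae	2.03	497.10	1.97E-09
B. bifidum DSM20456	1	Bifidobacteriaceae	2.67	289.39	4.78E-11
B. bifidum DSM20456	2	Bifidobacteriaceae	2.23	407.10	2.40E-08
L. casei DSM20011	1	Lactobacillaceae; L. casei	2.59	125.13	1.01E-04
L. casei DSM20011	2	Lactobacillaceae; L. casei	2.26	134.78	5.92E-04
Y. enterocolitica (faecal isolate)	1	Yersinia enterocolitica; Enterobacteriaceae	1.53	231.33	1.01E-05
Y. enterocolitica (faecal isolate)	2	Yersinia enterocolitica; Enterobacteriaceae	2.89	340.20	1.61E-06
B. cereus DSM31	1	Bacillus cereus et rel.	2.83	193.85	1.53E-06
B. cereus DSM31	2	Bacillus cereus et rel.	2.49	196.82	4.16E-03
B. adolescentis ATCC15703	1	Bifidobacteriaceae	4.10	732.95	3.95E-10
B. adolescentis ATCC15703	2	Bifidobacteriaceae	2.90	338.59	5.59E-07
L. rhamnosus DSM20021	1	Lactobacillaceae; L. casei	2.40	101.76	1.41E-03
L. rhamnosus DSM20021	2	Lactobacillaceae; L. casei	4.23	177.70	4.62E-07
L. delbrueckii DSM20074	1	Lactobacillaceae	3.77	210.11	2.24E-08
L. delbrueckii DSM20074	2	Lactobacillaceae	3.10	121.93	6.27E-08
L. pentosus DSM20314	1	Lactobacillaceae	3.05	131.65	4.58E-09
L. pentosus DSM20314	2	Lactobacillaceae	1.63	58.30	5.32E-07
L. acidophilus DSM20079	1	Lactobacillaceae	2.39	68.49	8.70E-05
L. acidophilus DSM20079	2	Lactobacillaceae	2.66	78.50	5.88E-06
L. reuteri DSM20016	1	Lactobacillaceae	3.17	150.57	4.66E-09
L. reuteri DSM20016	2	Lactobacillaceae	1.74	83.60	1.98E-07
L. plantarum DSM21074	1	Lactobacillaceae; L. plantarum	2.12	197.32	3.79E-09
L. plantarum DSM21074	2	Lactobacillaceae; L. plantarum	2.09	148.35	2.77E-08
C. difficile ATCCBAA1382	1	Clostridium XI; Clostridium difficile	1.12	238.87	4.88E-04
C. difficile ATCCBAA1382	2	Clostridium XI; Clostridium difficile	0.80	126.38	1.96E-03
C. jejuni ATCC33292	1	Campylobacter	0.70	19.89	5.29E-03
C. jejuni ATCC33292	2	Campylobacter	0.91	28.44	5.69E-03
V. parvula ATCC10790	1	Veillonella; Clostridium IX	1.12	205.66	1.57E-04
V. parvula ATCC10790	2	Veillonella; Clostridium IX	0.99	140.95	1.39E-04
B. breve DSM20091	1	Bifidobacteriaceae	2.22	570.01	6.22E-05
B. breve DSM20091	2	Bifidobacteriaceae	1.69	289.07	2.72E-04
B. longum ATCC15707	1	Bifidobacteriaceae; B. longum	1.76	341.94	1.64E-03
B. longum ATCC15707	2	Bifidobacteriaceae; B. longum	0.66	134.86	4.26E-02
R. productus ATCC23340	1	Clostridium XIVa	0.64	4.21	1.41E-03
R. productus ATCC23340	2	Clostridium XIVa	1.06	17.16	1.24E-06
L. salivarius SV2	1	Lactobacillaceae; L. salivarius	0.89	12.23	4.34E-04
L. salivarius SV2	2	Lactobacillaceae; L. salivarius	0.65	7.27	2.69E-05
E. faecalis ATCC700802	1	E. faecalis	3.12	306.51	1.09E-03
E. faecalis ATCC700802	2	E. faecalis	2.27	217.16	6.56E-03
C. leptum DSM73	1	Ruminococcus bromii; Clostridium IV	2.28	88.89	5.52E-07
C. leptum DSM73	2	Ruminococcus bromii; Clostridium IV	1.13	39.86	2.00E-07
R. albus DSM20455	1	Ruminococcus albus; Clostridium IV	1.46	47.05	2.50E-07
R. albus DSM20455	2	Ruminococcus albus; Clostridium IV	1.41	32.01	4.37E-06
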