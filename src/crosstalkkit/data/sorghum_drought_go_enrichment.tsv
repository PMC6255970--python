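go_id	ontology	description	k	K	p_value	fdr
GO:0006950	P	Response to stress	75	3705	3.90E-044	1.00E-041
GO:0009628	P	Response to abiotic stimulus	60	2423	3.70E-037	4.80E-035
GO:0009414	P	Response to water deprivation	31	374	1.70E-032	1.40E-030
GO:0009415	P	Response to water	31	393	6.90E-032	4.40E-030
GO:0050896	P	Response to stimulus	77	6230	1.40E-030	7.40E-029
GO:0009266	P	Response to temperature stimulus	34	902	5.70E-025	2.40E-023
GO:0042221	P	Response to chemical stimulus	53	3244	2.90E-023	1.10E-021
GO:0009409	P	Response to cold	27	625	3.60E-021	1.20E-019
GO:0009737	P	Response to abscisic acid stimulus	27	664	1.60E-020	4.60E-019
GO:0006970	P	Response to osmotic stress	25	631	9.70E-019	2.50E-017
GO:0010033	P	Response to organic substance	37	2117	2.80E-016	6.40E-015
GO:0009651	P	Response to salt stress	21	536	1.00E-015	2.20E-014
GO:0009725	P	Response to hormone stimulus	32	1601	1.50E-015	2.90E-014
GO:0009719	P	Response to endogenous stimulus	32	1755	1.80E-014	3.30E-013
GO:0070887	P	Cellular response to chemical stimulus	24	941	7.00E-014	1.20E-012
GO:0006979	P	Response to oxidative stress	20	605	1.20E-013	1.90E-012
GO:0009269	P	Response to desiccation	10	71	4.30E-013	6.50E-012
GO:0008152	P	Metabolic process	87	14876	1.30E-012	1.90E-011
GO:0051716	P	Cellular response to stimulus	28	1595	3.00E-012	3.80E-011
GO:0044248	P	Cellular catabolic process	26	1352	3.00E-012	3.80E-011
GO:0003824	F	Catalytic activity	97	13636	3.10E-028	2.70E-026
GO:0016491	F	Oxidoreductase activity	37	2349	7.20E-015	3.20E-013
GO:0016903	F	Oxidoreductase activity	10	145	3.00E-010	8.20E-009
GO:0016620	F	Oxidoreductase activity	9	104	3.70E-010	8.20E-009
GO:0004022	F	Alcohol dehydrogenase (NAD) activity	6	26	1.80E-009	2.20E-008
GO:0016774	F	Phosphotransferase activity	6	25	1.50E-009	2.20E-008
GO:0042624	F	ATPase activity uncoupled	6	26	1.80E-009	2.20E-008
GO:0008553	F	Hydrogen-exporting ATPase activity	6	47	4.30E-008	4.70E-007
GO:0004028	F	3-chloroallyl aldehyde dehydrogenase activity	5	24	6.80E-008	6.60E-007
GO:0016616	F	Oxidoreductase activity	10	271	9.00E-008	8.00E-007
GO:0016614	F	Oxidoreductase activity	10	315	3.50E-007	2.80E-006
GO:0016705	F	oxidoreductase activity	9	252	5.40E-007	3.90E-006
GO:0016765	F	Transferase activity	8	208	1.40E-006	9.40E-006
GO:0016740	F	Transferase activity	39	5115	2.20E-006	1.40E-005
GO:0000287	F	Magnesium ion binding	9	316	3.30E-006	1.80E-005
GO:0015662	F	ATPase activity coupled	6	104	3.40E-006	1.80E-005
GO:0008194	F	UDP-glycosyltransferase activity	9	341	6.00E-006	3.10E-005
GO:0042625	F	ATPase activity coupled	6	141	1.80E-005	8.70E-005
GO:0016757	F	transferase activity	12	768	3.00E-005	0.00013
GO:0016709	F	Oxidoreductase activity	5	93	3.20E-005	0.00013
GO:0005737	C	Cytoplasm	68	9051	1.10E-012	5.00E-011
GO:0044444	C	Cytoplasmic part	54	7660	5.10E-008	1.20E-006
GO:0009507	C	Chloroplast	23	1831	1.90E-007	2.20E-006
GO:0009536	C	Plastid	25	2109	1.50E-007	2.20E-006
GO:0044424	C	Intracellular part	69	12750	5.70E-006	5.40E-005
GO:0005622	C	Intracellular	69	13212	2.60E-005	0.0002
GO:0044464	C	Cell part	80	16988	9.60E-005	0.0005
GO:0044434	C	Chloroplast part	11	729	8.90E-005	0.0005
GO:0005623	C	Cell	80	16988	9.60E-005	0.0005
GO:0005739	C	Mitochondrion	18	1853	0.00015	0.00069
GO:0044435	C	Plastid part	11	793	0.00018	0.00078
GO:0009570	C	Chloroplast stroma	5	142	0.00022	0.00084
GO:0009532	C	Plastid stroma	5	191	0.0008	0.0029
GO:0005829	C	Cytosol	15	1740	0.0019	0.0062
GO:0019866	C	Organelle inner membrane	6	434	0.0058	0.018
GO:0005743	C	Mitochondrial inner membrane	5	325	0.0075	0.022
GO:0031090	C	Organelle membrane	13	1762	0.013	0.037
GO:0031966	C	Mitochondrial membrane	5	381	0.014	0.037
GO:0044429	C	Mitochondrial part	6	546	0.016	0.04
GO:0043231	C	Intracellular membrane-bounded organelle	49	10385	0.019	0.04
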