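marker_name	chain	span	nominal_mz	sequence	taxon
2T3	COL1A2	10-42	2975	GPPGASGPPGAQGFQGPAGEPGEPGQTGPAGAR	
2T3	COL1A2	10-42	2989	GPPGATGPPGAQGFQGPAGEPGEPGQTGPAGAR	
2T3	COL1A2	10-42	2991	GPPGASGPPGAQGFQGPAGEPGEPGQTGPAGSR	
2T3	COL1A2	10-42	3009	GPPGASGPPGAQGFQGPAGEPGEDGQTGPAGAR	
889-906	COL1A2	889-906	1606	GEPGPVGSVGPVGPTGAR	
889-906	COL1A2	889-906	1624	GEPGPAGSVGPVGPFGAR	
889-906	COL1A2	889-906	1652	GEPGPVGSVGPVGPFGAR	
A	COL1A2	978-990	1137	PGNAGAVGPAGLR	
A	COL1A2	978-990	1150	PGQAGAVGPAGLR	
A	COL1A2	978-990	1159	PGHAGAVGPAGLR	
A	COL1A2	978-990	1182	SGQPGTVGPAGVR	
B	COL1A2	484-498	1397	GVAGEFGLPGPAGPR	
B	COL1A2	484-498	1411	GPAGEFGLPGPAGPR	
B	COL1A2	484-498	1427	GSPGEFGLPGPAGPR	
B	COL1A2	484-498	1439	GVPGEFGLPGPAGPR	
B	COL1A2	484-498	1453	GLPGEFGLPGPAGPR	
C	COL1A2	502-519	1598	GPPGESGAVGPTGSIGSR	
C	COL1A2	502-519	1607	GPPGESGAAGPTGPLGNR	
D	COL1A2	793-816	2119	GLPGVSGSLGEPGPLGIAGPAGAR	
D	COL1A2	793-816	2145	GLPGVSGALGEPGPLGIAGPPGAR	
D	COL1A2	793-816	2161	GLPGVSGSLGEPGPLGIAGPPGAR	
D	COL1A2	793-816	2163	GLPGVSGSVGEPGPLGISGPPGAR	
D	COL1A2	793-816	2177	GLPGVSGSLGEPGPLGISGPPGAR	
E	COL1A2	454-483	2335	GEQGPAGPPGFQGLPGPSGPAGEGGK	
E	COL1A2	454-483	2848	GEQGPAGPPGFQGLPGPSGPAGEVGKPGER	
F	COL1A1	586-618	2869	GLTGPIGPPGPAGPSGDKGESGPSGPAGPTGAR	
F	COL1A1	586-618	2873	GLTGPIGPPGPAGTSGDKGESGPSGPAGPTGAR	
F	COL1A1	586-618	2881	GLTGPIGPPGPAGPAGDKGESGPSGPVGPTGAR	
F	COL1A1	586-618	2897	GLTGPIGPPGPAGPSGDKGESGPSGPVGPTGAR	
G	COL1A2	757-789	2929	GPPGEAGASGPPGSSGPQGLLGAPGILGLPGSR	
G	COL1A2	757-789	2943	GPPGEAGATGPPGSSGPQGLLGAPGILGLPGSR	
G	COL1A2	757-789	2945	GPEGEAGASGPPGSSGPQGLLGAPGILGLPGSR	
G	COL1A2	757-789	2957	GPPGESGAVGPPGSSGPQGLLGAPGILGLPGSR	
G	COL1A2	757-789	2959	GPPGESGATGPPGSSGPQGLLGAPGILGLPGSR	
G	COL1A2	757-789	2971	GPPGESGALGPPGSSGPQGLLGAPGILGLPGSR	
G	COL1A2	757-789	2999	GPPGEAGATGPPGSSGPQGLWGAPGILGLPGSR	
P1	COL1A1	508-519	1120	GVQGPAGPQGPR	
P1	COL1A1	508-519	1162	GVQGPPGPQGPR	
P2	COL1A2	292-309	1650	GPNGEPGSTGPSGPPGLR	
P2	COL1A2	292-309	1680	GPNGEPGSTGPTGPPGLR	
P2	COL1A2	292-309	1692	GPNGEPGSTGPPGPPGLR	
P2	COL1A2	292-309	1725	GPNGEPGSTGPMGPPGLR	
D	COL1A2	793-816	2121	GLPGVSGSVGEPGPLGIAGPAGAR	Thylacinus cynocephalus
D	COL1A2	793-816	2121	GLPGVSGGLGEPGPLGLSGPSGAR	Tachyglossus aculeatus
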