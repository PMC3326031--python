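modification	residue	position	source	sumo_type	experimental
phospho	S	367	GPS 2.1	none	true
phospho	S	403	GPS 2.1	none	false
phospho	S	475	GPS 2.1	none	false
phospho	S	875	GPS 2.1	none	false
phospho	S	1360	GPS 2.1	none	false
phospho	S	1635	GPS 2.1	none	false
phospho	S	1981	GPS 2.1	none	true
phospho	S	2242	GPS 2.1	none	false
phospho	S	2592	GPS 2.1	none	false
phospho	S	2761	GPS 2.1	none	false
phospho	S	2941	GPS 2.1	none	false
phospho	T	373	GPS 2.1	none	true
methyl	R	329	MeMo	none	false
methyl	R	493	MeMo	none	false
methyl	R	832	MeMo	none	false
methyl	R	2719	MeMo	none	false
methyl	R	2811	MeMo	none	false
methyl	K	331	MeMo	none	false
methyl	K	573	MeMo	none	false
methyl	K	1066	MeMo	none	false
methyl	K	1109	MeMo	none	false
methyl	K	1196	MeMo	none	false
methyl	K	1330	MeMo	none	false
methyl	K	1772	MeMo	none	false
methyl	K	1992	MeMo	none	false
methyl	K	2266	MeMo	none	false
methyl	K	2331	MeMo	none	false
methyl	K	2418	MeMo	none	false
methyl	K	2585	MeMo	none	false
methyl	K	2700	MeMo	none	false
n_glyc	N	81	NetNGlyc 1.0	none	false
n_glyc	N	272	NetNGlyc 1.0	none	false
n_glyc	N	704	NetNGlyc 1.0	none	false
n_glyc	N	765	NetNGlyc 1.0	none	false
n_glyc	N	789	NetNGlyc 1.0	none	false
n_glyc	N	1230	NetNGlyc 1.0	none	false
n_glyc	N	1240	NetNGlyc 1.0	none	false
n_glyc	N	1719	NetNGlyc 1.0	none	false
n_glyc	N	1983	NetNGlyc 1.0	none	false
o_glyc	T	2666	NetOGlyc 3.1	none	false
o_glyc	T	2902	NetOGlyc 3.1	none	false
sumo	K	24	SUMOsp 2.0	none	false
sumo	K	477	SUMOsp 2.0	none	false
sumo	K	640	SUMOsp 2.0	none	false
sumo	K	892	SUMOsp 2.0	none	false
sumo	K	1323	SUMOsp 2.0	none	false
sumo	K	2153	SUMOsp 2.0	none	false
sumo	K	2302	SUMOsp 2.0	none	false
sumo	K	2421	SUMOsp 2.0	none	false
sumo	K	2456	SUMOsp 2.0	none	false
sumo	K	2687	SUMOsp 2.0	none	false
acetyl	K	24	PAIL	none	false
acetyl	K	25	PAIL	none	false
acetyl	K	29	PAIL	none	false
acetyl	K	31	PAIL	none	false
acetyl	K	41	PAIL	none	false
acetyl	K	50	PAIL	none	false
acetyl	K	53	PAIL	none	false
acetyl	K	79	PAIL	none	false
acetyl	K	93	PAIL	none	false
acetyl	K	102	PAIL	none	false
acetyl	K	106	PAIL	none	false
acetyl	K	116	PAIL	none	false
acetyl	K	224	PAIL	none	true
acetyl	K	296	PAIL	none	false
acetyl	K	300	PAIL	none	false
acetyl	K	331	PAIL	none	false
acetyl	K	342	PAIL	none	false
acetyl	K	385	PAIL	none	false
acetyl	K	387	PAIL	none	false
acetyl	K	388	PAIL	none	false
acetyl	K	397	PAIL	none	false
acetyl	K	468	PAIL	none	false
acetyl	K	556	PAIL	none	false
acetyl	K	640	PAIL	none	false
acetyl	K	687	PAIL	none	false
acetyl	K	750	PAIL	none	false
acetyl	K	792	PAIL	none	false
acetyl	K	793	PAIL	none	false
acetyl	K	797	PAIL	none	false
acetyl	K	926	PAIL	none	false
acetyl	K	1109	PAIL	none	false
acetyl	K	1170	PAIL	none	false
acetyl	K	1178	PAIL	none	false
acetyl	K	1181	PAIL	none	false
acetyl	K	1192	PAIL	none	false
acetyl	K	1280	PAIL	none	false
acetyl	K	1398	PAIL	none	false
acetyl	K	1400	PAIL	none	false
acetyl	K	1435	PAIL	none	true
acetyl	K	1454	PAIL	none	false
acetyl	K	1510	PAIL	none	false
acetyl	K	1582	PAIL	none	false
acetyl	K	1615	PAIL	none	false
acetyl	K	1665	PAIL	none	false
acetyl	K	1692	PAIL	none	false
acetyl	K	1701	PAIL	none	false
acetyl	K	1738	PAIL	none	false
acetyl	K	1772	PAIL	none	false
acetyl	K	1773	PAIL	none	false
acetyl	K	1782	PAIL	none	false
acetyl	K	1820	PAIL	none	false
acetyl	K	1834	PAIL	none	false
acetyl	K	1903	PAIL	none	false
acetyl	K	1964	PAIL	none	false
acetyl	K	1965	PAIL	none	false
acetyl	K	1992	PAIL	none	false
acetyl	K	1994	PAIL	none	false
acetyl	K	2025	PAIL	none	false
acetyl	K	2117	PAIL	none	false
acetyl	K	2148	PAIL	none	false
acetyl	K	2213	PAIL	none	false
acetyl	K	2303	PAIL	none	false
acetyl	K	2331	PAIL	none	false
acetyl	K	2383	PAIL	none	false
acetyl	K	2385	PAIL	none	false
acetyl	K	2418	PAIL	none	true
acetyl	K	2421	PAIL	none	false
acetyl	K	2440	PAIL	none	false
acetyl	K	2456	PAIL	none	false
acetyl	K	2460	PAIL	none	false
acetyl	K	2585	PAIL	none	false
acetyl	K	2589	PAIL	none	false
acetyl	K	2639	PAIL	none	false
acetyl	K	2687	PAIL	none	false
acetyl	K	2710	PAIL	none	false
acetyl	K	2717	PAIL	none	false
acetyl	K	2747	PAIL	none	false
acetyl	K	2789	PAIL	none	false
acetyl	K	2804	PAIL	none	false
acetyl	K	2848	PAIL	none	false
acetyl	K	2992	PAIL	none	false
acetyl	K	3018	PAIL	none	true
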