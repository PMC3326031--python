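variant_id	gene	protein_position	wild_aa	mutant_aa	region	validation_status	sift_score	polyphen_psic	imutant_ddg	consurf_score	exposure	pupasuite_element	utrscan_patterns	fastsnp_risk	fastsnp_effect
VAR_010798	ATM	49	S	C	coding_nonsyn	unknown	.	.	.	4	exposed	.	.	.	.
VAR_041546	ATM	140	D	H	coding_nonsyn	unknown	.	.	.	9	exposed	.	.	.	.
rs35963548	ATM	532	C	Y	coding_nonsyn	unknown	.	.	.	5	buried	.	.	.	.
VAR_041557	ATM	872	P	S	coding_nonsyn	unknown	.	.	.	1	exposed	.	.	.	.
VAR_056683	ATM	942	L	F	coding_nonsyn	unknown	.	.	.	5	buried	.	.	.	.
rs12788429	ATM	1161	V	G	coding_nonsyn	unknown	.	.	.	7	buried	.	.	.	.
rs35962982	ATM	1590	L	F	coding_nonsyn	unknown	.	.	.	3	buried	.	.	.	.
VAR_056688	ATM	2034	R	Q	coding_nonsyn	unknown	.	.	.	6	buried	.	.	.	.
VAR_010853	ATM	2423	E	G	coding_nonsyn	unknown	.	.	.	8	exposed	.	.	.	.
VAR_010854	ATM	2424	V	G	coding_nonsyn	unknown	.	.	.	8	exposed	.	.	.	.
VAR_010856	ATM	2438	T	I	coding_nonsyn	unknown	.	.	.	8	exposed	.	.	.	.
VAR_056690	ATM	2570	E	G	coding_nonsyn	unknown	.	.	.	2	exposed	.	.	.	.
VAR_010863	ATM	2625	D	Q	coding_nonsyn	unknown	.	.	.	7	exposed	.	.	.	.
rs28942103	ATM	2677	Y	C	coding_nonsyn	unknown	.	.	.	9	exposed	.	.	.	.
VAR_041582	ATM	2842	P	R	coding_nonsyn	unknown	.	.	.	7	buried	.	.	.	.
VAR_010886	ATM	2867	G	R	coding_nonsyn	unknown	.	.	.	9	buried	.	.	.	.
rs56887719	ATM	2907	P	L	coding_nonsyn	unknown	.	.	.	9	exposed	.	.	.	.
VAR_010890	ATM	2909	E	G	coding_nonsyn	unknown	.	.	.	9	exposed	.	.	.	.
rs1137889	ATM	3003	N	D	coding_nonsyn	unknown	.	.	.	8	exposed	.	.	.	.
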