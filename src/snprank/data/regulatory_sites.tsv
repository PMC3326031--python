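variant_id	region	pupasuite_element	utrscan_patterns	fastsnp_risk	fastsnp_effect	bold
rs12284748	mrna	ESE	K-BOX	.	.	true
rs11558526	mrna	ESE	.	.	.	false
rs4987113	mrna	ESE	15-LOX-DICE,IRES	.	.	true
rs4987114	mrna	ESE	.	.	.	false
rs3218711	mrna	ESE	.	.	.	false
rs3092852	mrna	ESE	.	.	.	false
rs3092845	mrna	ESE	IRES	.	.	true
rs3092836	mrna	ESS	.	.	.	false
rs3092834	mrna	ESE	.	.	.	false
rs1137918	mrna	ESE	.	.	.	false
rs453848	mrna	ESE	.	.	.	false
rs378840	mrna	ESE	.	.	.	false
rs227092	mrna	ESE	IRES,K-BOX	.	.	true
rs227091	mrna	ESE	15-LOX-DICE	.	.	true
rs189037	mrna	ESE	.	.	.	false
rs4585	mrna	ESE	15-LOX-DICE,IRES	.	.	true
rs55900855	utr3	none	IRES	.	.	false
rs4987114	utr3	none	15-LOX-DICE,IRES	.	.	false
rs12284801	utr3	none	IRES,K-BOX	.	.	false
rs4988000	utr3	none	IRES	.	.	false
rs3218697	utr3	none	IRES	.	.	false
rs3092844	utr3	none	IRES	.	.	false
rs3092837	utr3	none	IRES,K-BOX	.	.	false
rs4987880	utr5	none	.	.	Promoter/regulatory region	false
rs4986839	intron	none	.	.	splicing site	false
rs3092829	intron	none	.	.	splicing site	false
rs3092872	intron	none	.	.	splicing site	false
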