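sample_id	province	n_reads	n_retained_reads	n_alleles	n_private	n_novel
H1	Bologna	173064	149678	17	8	9
H2	Reggio Emilia	75454	72027	13	4	5
H3	Piacenza	414002	269785	40	16	13
H4	Reggio Emilia	84307	82056	14	2	5
H5	Reggio Emilia	397333	296982	20	7	5
H6	Ferrara	34350	33503	13	3	7
H7	Piacenza	99979	48369	23	11	12
H8	Bologna	41741	37431	17	4	3
H9	Piacenza	97735	73994	33	13	16
H10	Rimini	70307	53728	61	41	40
H11	Piacenza	35183	29865	10	2	3
H12	Piacenza	1341	1220	10	3	0
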