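name	sequence	length	abundance	chromosome	context
Can_miR_01	ACGGAAAAUCAUGGCUGCACUUAA	24	26	1	Intergenic
Can_miR_02	AAUCAAGUUAGGAACCAUGCAAGU	24	2	6	3'UTR
Can_miR_03	ACUCUAUAUGAACUAAGAUCG	21	6	8	Intergenic
Can_miR_04	UUGGCUGCAUCCCGUUCUCCUC	22	7	4	Intergenic
Can_miR_05	AGCUGCCGACUCAUUCACCCA	21	30	1	Intergenic
Can_miR_06	UCUCUCUCUCCCUUGAAGGCU	21	3	11	Intergenic
Can_miR_07	AUGAAUGUAGGUAAUGCUAGAAAG	24	3	1	Intergenic
Can_miR_08	GAAUGAUCAAAGUUGGACACGAA	23	8	1	Intron
Can_miR_09	ACCUCAACAUGGUAUCAGAACUGG	24	8	7	Intron
Can_miR_10	UCAAUAGCGAUCAAGGCGGAC	21	3	7	Intergenic
Can_miR_11	UGGGAAAGGACCAUAAUACCCCUA	24	7	3	Intron
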