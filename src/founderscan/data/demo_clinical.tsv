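family_id	sample_id	genotype_class	is_index	onset_age	biopsy_fsgs_age	proteinuria_g_day	edema_at_onset	esrd	esrd_age	ckd_stage
144	144/I	biallelic	1	childhood	35	11	N	N		G1A2
78	78/I	biallelic	1	24	25		N	Y	37	ESRD/Tx
115	115/I	biallelic	1	3	40	1	N	N		G1A3
109	109/I	biallelic	1	41	41	3	Y	N		G4A3
209	209/I	biallelic	1	childhood	15	13	N	Y	33	ESRD/Tx
209	209/II	biallelic	0	18		 	N	N		G1A2
209	209/III	het	0	68		3.5	Y	N		G1A3
123	123/I	het	1	39	39	5	Y	N		G1A1
68	68/I	het	1	72	72	17	Y	N		G1A1
104	104/I	het	1	63	63	4	Y	N		G1A1
75	75/I	het	1	25	25	9.45	Y	N		G3A2
142	142/I	het	1	27	27		N	Y	39	ESRD
902	902/I	biallelic_other	1	1	27	8	N	Y	38	ESRD/Tx
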