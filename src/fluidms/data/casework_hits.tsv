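# Protein-hit rows from five real casework (rape-case) samples of the same
# validation study, entered at accession level.
sample_id	accession	n_peptides	protein_score	best_peptide_p
washcloth_6mo	SEMG1_HUMAN	4	174	1e-05
sweater_1y	SEMG2_HUMAN	19	819	4.6e-17
sweater_1y	SEMG1_HUMAN	15	630	2.7e-15
sweater_1y	PAP_HUMAN	4	125	0.00029
sweater_1y	AMY1_HUMAN	2	197	2.8e-15
underpants_2y	PAP_HUMAN	1	73	3.5e-05
underpants_2y	SPR1A_HUMAN	3	44	0.03
underpants_5y	SEMG2_HUMAN	18	510	2.9e-08
underpants_5y	SEMG1_HUMAN	20	492	4.3e-08
underpants_5y	PAP_HUMAN	5	152	4e-05
underpants_5y	PSA_HUMAN	1	72	4.9e-05
underpants_5y	CORNU_HUMAN	1	91	5.3e-07
underpants_8y	PSA_HUMAN	4	182	3.2e-07
underpants_8y	CORNU_HUMAN	1	67	0.00015
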