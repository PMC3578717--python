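# Protein-hit rows of a published blind validation experiment (15 samples,
# pure matrices and mixtures on soiled fabric), entered at accession level.
# Sample X1 contained no biological matrix and therefore has no rows.
sample_id	accession	n_peptides	protein_score	best_peptide_p
Z1	SEMG1_HUMAN	39	1094	1.1e-08
Z1	SEMG2_HUMAN	30	1009	3.7e-12
Z1	PAP_HUMAN	4	156	1e-05
Z1	PSA_HUMAN	1	82	4.1e-06
Z2	CORNU_HUMAN	1	81	5.2e-06
Z2b	CORNU_HUMAN	4	239	8.4e-08
Z2b	SPR1B_HUMAN	2	130	2.4e-08
Z3	HBB_BOVIN	27	904	1.3e-07
Z3	HBA_BOVIN	15	847	4.5e-14
Z4	HBB_HUMAN	24	905	5.4e-10
Z4	HBA_HUMAN	7	348	1.8e-07
Z5	AMY1_HUMAN	1	63	0.00034
Z5b	AMY1_HUMAN	14	813	3.8e-11
Z6	SEMG2_HUMAN	35	1158	2.3e-09
Z6	SEMG1_HUMAN	32	828	6.9e-09
Z6	PAP_HUMAN	3	179	1.9e-07
Z6	PSA_HUMAN	2	113	1.5e-05
W	SEMG2_HUMAN	21	737	1.3e-09
W	SEMG1_HUMAN	24	659	5.7e-06
W	CORNU_HUMAN	5	656	1.9e-22
W	PAP_HUMAN	1	89	8.3e-07
W	SPR1B_HUMAN	2	84	0.00074
W	INVO_HUMAN	1	46	0.018
X2	HBB_HUMAN	36	1203	5.6e-10
X2	HBA_HUMAN	16	795	9.3e-17
X2	SEMG2_HUMAN	6	271	2.2e-09
X2	SEMG1_HUMAN	2	76	0.00016
X3	HBB_HUMAN	10	254	9.5e-08
X3	HBA_HUMAN	6	254	8.8e-08
X4	SEMG2_HUMAN	35	1793	8.1e-23
X4	SEMG1_HUMAN	41	1337	2.2e-15
X4	AMY1_HUMAN	6	244	6e-10
X4	PSA_HUMAN	5	207	3.5e-06
X4	PAP_HUMAN	5	205	1.7e-07
X5	HBB_HUMAN	39	1187	5.9e-10
X5	HBA_HUMAN	15	807	2.6e-18
X5	AMY1_HUMAN	3	129	1.4e-05
X6	HBB_BOVIN	24	860	1.3e-07
X6	HBA_BOVIN	13	787	1.3e-15
X6	AMY1_HUMAN	3	160	3.1e-07
X7	SEMG2_HUMAN	25	891	4.3e-10
X7	SEMG1_HUMAN	28	712	9.4e-07
X7	CORNU_HUMAN	2	219	1.9e-12
X7	PAP_HUMAN	5	201	1e-07
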