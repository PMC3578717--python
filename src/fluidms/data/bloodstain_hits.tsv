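# Protein-hit rows from seven benzidine-positive casework stains of the
# same validation study; every sample showed hemoglobin.
sample_id	accession	n_peptides	protein_score	best_peptide_p
car_door_1	HBB_HUMAN	36	968	1.3e-12
car_door_1	HBA_HUMAN	25	818	6.1e-11
car_door_2	HBB_HUMAN	6	140	3.4e-06
car_door_2	HBA_HUMAN	3	53	0.037
envelope_back	HBB_HUMAN	7	127	1.6e-05
envelope_back	HBA_HUMAN	4	93	7.6e-07
swab_unknown	HBB_HUMAN	32	905	3e-13
swab_unknown	HBA_HUMAN	18	584	7.1e-13
sweater_swab	HBB_HUMAN	16	555	1.2e-13
sweater_swab	HBA_HUMAN	13	358	2.6e-08
envelope_stain	HBB_HUMAN	43	838	2.4e-10
envelope_stain	HBA_HUMAN	16	354	7.2e-07
shower_swab	HBB_HUMAN	39	768	4.9e-10
shower_swab	HBA_HUMAN	23	479	2.6e-11
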