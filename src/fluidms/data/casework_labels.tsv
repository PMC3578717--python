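sample_id	matrices	blood_species
washcloth_6mo	semen	.
sweater_1y	semen;saliva	.
underpants_2y	semen;vaginal_fluid	.
underpants_5y	semen;vaginal_fluid	.
underpants_8y	semen;vaginal_fluid	.
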