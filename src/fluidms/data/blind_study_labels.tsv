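# Expected identifications for the blind-study hit rows.  `matrices` is a
# semicolon list of matrix labels; `blood_species` is the expected species
# call for the hemoglobin group ('.' when blood is absent or unstated).
sample_id	matrices	blood_species
Z1	semen	.
Z2	vaginal_fluid	.
Z2b	vaginal_fluid	.
Z3	blood	Bos taurus
Z4	blood	Homo sapiens
Z5	saliva	.
Z5b	saliva	.
Z6	semen	.
W	semen;vaginal_fluid	.
X1	none	.
X2	blood;semen	Homo sapiens
X3	blood	Homo sapiens
X4	semen;saliva	.
X5	blood;saliva	Homo sapiens
X6	blood;saliva	Bos taurus
X7	semen;vaginal_fluid	.
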