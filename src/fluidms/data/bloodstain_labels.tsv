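sample_id	matrices	blood_species
car_door_1	blood	Homo sapiens
car_door_2	blood	Homo sapiens
envelope_back	blood	Homo sapiens
swab_unknown	blood	Homo sapiens
sweater_swab	blood	Homo sapiens
envelope_stain	blood	Homo sapiens
shower_swab	blood	Homo sapiens
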