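version: default
rules:
  blood:
    markers: [HBB_HUMAN, HBA_HUMAN, HBB_BOVIN, HBA_BOVIN, HBB_CANFA, HBA_CANFA]
    sufficiency: specific_sufficient
    species_resolvable: true
  semen:
    markers: [SEMG1_HUMAN, SEMG2_HUMAN, PAP_HUMAN, PSA_HUMAN]
    sufficiency: specific_sufficient
  vaginal_fluid:
    markers: [CORNU_HUMAN, SPR1A_HUMAN, SPR1B_HUMAN, INVO_HUMAN]
    sufficiency: specific_sufficient
  saliva:
    markers: [AMY1_HUMAN]
    sufficiency: specific_sufficient
    isoform_group: amylase
  nasal_secretion:
    markers: [PLUNC_HUMAN]
    sufficiency: specific_sufficient
    support: [ALBU_HUMAN, IGJ_HUMAN, IGKC_HUMAN, IGHA_HUMAN]
  urine:
    markers: [UROM_HUMAN, AMBP_HUMAN]
    sufficiency: conditional
    required_absent: [HBB_HUMAN, HBA_HUMAN, HBB_BOVIN, HBA_BOVIN, HBB_CANFA, HBA_CANFA]
    absence_excludes: false
  feces:
    markers: [IGJ_HUMAN, IGKC_HUMAN, IGHA_HUMAN, ALBU_HUMAN]
    sufficiency: conditional
    required_absent: [HBB_HUMAN, HBA_HUMAN, HBB_BOVIN, HBA_BOVIN, HBB_CANFA, HBA_CANFA]
    absence_excludes: false
    nonspecific: true
groups:
  amylase: [AMY1_HUMAN, AMY2_HUMAN]
  hemoglobin: [HBB_HUMAN, HBA_HUMAN, HBB_BOVIN, HBA_BOVIN, HBB_CANFA, HBA_CANFA]
aliases:
  hemoglobin: [HBB_HUMAN, HBA_HUMAN, HBB_BOVIN, HBA_BOVIN, HBB_CANFA, HBA_CANFA]
  cornifin: [SPR1A_HUMAN, SPR1B_HUMAN]
  immunoglobulins: [IGJ_HUMAN, IGKC_HUMAN, IGHA_HUMAN]
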