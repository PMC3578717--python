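# Synthetic composition profiles used by the sample simulator.
#
# `abundances` are relative within-matrix protein weights (not measured
# values); `richness` separates protein-rich matrices (blood, semen) from
# protein-poor ones (saliva, vaginal fluid, ...), which drives the masking
# of poor matrices inside rich ones.  `matrix` is the biological matrix a
# profile represents: several profiles (species variants of blood) can map
# to the same matrix.
richness_yield:
  high: 1.0
  low: 0.05
profiles:
  blood:
    matrix: blood
    richness: high
    abundances:
      HBB_HUMAN: 0.40
      HBA_HUMAN: 0.30
      ALBU_HUMAN: 0.20
      IGKC_HUMAN: 0.05
      IGHA_HUMAN: 0.05
  blood_bovine:
    matrix: blood
    richness: high
    abundances:
      HBB_BOVIN: 0.40
      HBA_BOVIN: 0.30
      ALBU_HUMAN: 0.30
  blood_canine:
    matrix: blood
    richness: high
    abundances:
      HBB_CANFA: 0.40
      HBA_CANFA: 0.30
      ALBU_HUMAN: 0.30
  semen:
    matrix: semen
    richness: high
    abundances:
      SEMG1_HUMAN: 0.32
      SEMG2_HUMAN: 0.30
      PAP_HUMAN: 0.12
      PSA_HUMAN: 0.10
      ALBU_HUMAN: 0.10
      AMY2_HUMAN: 0.06
  saliva:
    matrix: saliva
    richness: low
    abundances:
      AMY1_HUMAN: 0.75
      ALBU_HUMAN: 0.15
      IGHA_HUMAN: 0.10
  vaginal_fluid:
    matrix: vaginal_fluid
    richness: low
    abundances:
      CORNU_HUMAN: 0.35
      SPR1B_HUMAN: 0.20
      SPR1A_HUMAN: 0.15
      INVO_HUMAN: 0.15
      ALBU_HUMAN: 0.10
      AMY2_HUMAN: 0.05
  nasal_secretion:
    matrix: nasal_secretion
    richness: low
    abundances:
      PLUNC_HUMAN: 0.40
      ALBU_HUMAN: 0.30
      IGHA_HUMAN: 0.10
      IGKC_HUMAN: 0.10
      IGJ_HUMAN: 0.10
  urine:
    matrix: urine
    richness: low
    abundances:
      UROM_HUMAN: 0.60
      AMBP_HUMAN: 0.25
      ALBU_HUMAN: 0.15
  feces:
    matrix: feces
    richness: low
    abundances:
      IGJ_HUMAN: 0.30
      IGKC_HUMAN: 0.25
      IGHA_HUMAN: 0.25
      ALBU_HUMAN: 0.20
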