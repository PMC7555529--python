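# Reference cohort: 31 androgenetic dispermic complete hydatidiform moles.
# Constitution per case (sex constitution, extra chromosomes with parental
# origin, biparental disomic chromosomes) and post-molar outcome
# (SR = spontaneous remission, GTN = gestational trophoblastic neoplasia).
# Composition: 22 euploid cases (9 XX, 13 XY); 8 autosomal-trisomy cases of
# which one is a double trisomy; 1 XYY case; 7 maternal-origin and 3
# paternal-origin extra chromosomes (the XYY's extra Y counts as paternal);
# 3 biparental disomic chromosomes.
cases:
  - {id: HM01, mode: dispermic_CHM, sex: XX, outcome: SR}
  - {id: HM02, mode: dispermic_CHM, sex: XX, outcome: SR}
  - id: HM03
    mode: dispermic_CHM
    sex: XY
    extra_chromosomes: [{chromosome: "22", origin: maternal}]
    outcome: SR
  - {id: HM04, mode: dispermic_CHM, sex: XY, outcome: GTN}
  - {id: HM05, mode: dispermic_CHM, sex: XYY, outcome: GTN}
  - {id: HM06, mode: dispermic_CHM, sex: XY, outcome: GTN}
  - {id: HM07, mode: dispermic_CHM, sex: XX, outcome: SR}
  - {id: HM08, mode: dispermic_CHM, sex: XY, outcome: SR}
  - {id: HM09, mode: dispermic_CHM, sex: XX, outcome: SR}
  - id: HM10
    mode: dispermic_CHM
    sex: XX
    extra_chromosomes:
      - {chromosome: "7", origin: maternal}
      - {chromosome: "11", origin: maternal}
    biparental_disomies: ["4"]
    outcome: SR
  - id: HM11
    mode: dispermic_CHM
    sex: XY
    extra_chromosomes: [{chromosome: "13", origin: maternal}]
    biparental_disomies: ["6"]
    outcome: SR
  - {id: HM12, mode: dispermic_CHM, sex: XX, outcome: SR}
  - id: HM13
    mode: dispermic_CHM
    sex: XY
    extra_chromosomes: [{chromosome: "6", origin: maternal}]
    outcome: SR
  - {id: HM14, mode: dispermic_CHM, sex: XX, outcome: SR}
  - id: HM15
    mode: dispermic_CHM
    sex: XX
    extra_chromosomes: [{chromosome: "14", origin: paternal}]
    outcome: GTN
  - {id: HM16, mode: dispermic_CHM, sex: XY, outcome: GTN}
  - id: HM17
    mode: dispermic_CHM
    sex: XY
    extra_chromosomes: [{chromosome: "3", origin: paternal}]
    outcome: SR
  - {id: HM18, mode: dispermic_CHM, sex: XY, outcome: SR}
  - {id: HM19, mode: dispermic_CHM, sex: XX, outcome: GTN}
  - {id: HM20, mode: dispermic_CHM, sex: XX, outcome: SR}
  - id: HM21
    mode: dispermic_CHM
    sex: XY
    extra_chromosomes: [{chromosome: "7", origin: maternal}]
    outcome: SR
  - {id: HM22, mode: dispermic_CHM, sex: XX, outcome: GTN}
  - {id: HM23, mode: dispermic_CHM, sex: XY, outcome: SR}
  - id: HM24
    mode: dispermic_CHM
    sex: XY
    extra_chromosomes: [{chromosome: "15", origin: maternal}]
    biparental_disomies: ["2"]
    outcome: SR
  - {id: HM25, mode: dispermic_CHM, sex: XY, outcome: SR}
  - {id: HM26, mode: dispermic_CHM, sex: XY, outcome: SR}
  - {id: HM27, mode: dispermic_CHM, sex: XY, outcome: SR}
  - {id: HM28, mode: dispermic_CHM, sex: XY, outcome: SR}
  - {id: HM29, mode: dispermic_CHM, sex: XY, outcome: SR}
  - {id: HM30, mode: dispermic_CHM, sex: XY, outcome: SR}
  - {id: HM31, mode: dispermic_CHM, sex: XY, outcome: SR}
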