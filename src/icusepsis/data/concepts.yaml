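# Concept map for the synthetic vocabulary: raw item name -> clinical concept.
# Users with access to the real database supply their own map from item
# identifiers to these concepts; rows whose item is absent are dropped.
numericitems:
  pao2: {concept: pao2, unit: kPa}
  fio2: {concept: fio2, unit: fraction}
  platelets: {concept: platelets, unit: 1e9/L}
  bilirubin: {concept: bilirubin, unit: umol/L}
  mean_abp: {concept: map, unit: mmHg}
  gcs_total: {concept: gcs, unit: points}
  creatinine: {concept: creatinine, unit: umol/L}
  urine_output_24h: {concept: urine_output, unit: mL/day}
  lactate: {concept: lactate, unit: mmol/L}
drugitems:
  norepinephrine: {concept: vasopressor, unit: ug/kg/min}
  epinephrine: {concept: vasopressor, unit: ug/kg/min}
  dopamine: {concept: vasopressor, unit: ug/kg/min}
  dobutamine: {concept: vasopressor, unit: ug/kg/min}
  benzylpenicillin: {concept: antibiotic}
  flucloxacillin: {concept: antibiotic}
  amoxicillin: {concept: antibiotic}
  cefazolin: {concept: antibiotic}
  doxycycline: {concept: antibiotic}
  erythromycin: {concept: antibiotic}
  amoxicillin-clavulanate: {concept: antibiotic}
  cefuroxime: {concept: antibiotic}
  cefotaxime: {concept: antibiotic}
  ceftriaxone: {concept: antibiotic}
  ciprofloxacin: {concept: antibiotic}
  clindamycin: {concept: antibiotic}
  gentamicin: {concept: antibiotic}
  metronidazole: {concept: antibiotic}
  piperacillin-tazobactam: {concept: antibiotic}
  ceftazidime: {concept: antibiotic}
  cefepime: {concept: antibiotic}
  vancomycin: {concept: antibiotic}
  tobramycin: {concept: antibiotic}
  meropenem: {concept: antibiotic}
  imipenem: {concept: antibiotic}
  linezolid: {concept: antibiotic}
  caspofungin: {concept: antibiotic}
listitems:
  mechanical_ventilation: {concept: ventilated}
  admission_form_sepsis: {concept: admission_form_sepsis_flag}
  admission_diagnosis: {concept: admission_diagnosis}
  culture_drawn: {concept: culture_drawn}
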