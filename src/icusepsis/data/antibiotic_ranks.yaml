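# Illustrative antibiotic escalation ranks: 1 = narrow spectrum ... 4 = reserve.
# The rank contents are site-specific configuration, not part of the method;
# replace this formulary with your institution's classification.
ranks:
  benzylpenicillin: 1
  flucloxacillin: 1
  amoxicillin: 1
  cefazolin: 1
  doxycycline: 1
  erythromycin: 1
  amoxicillin-clavulanate: 2
  cefuroxime: 2
  cefotaxime: 2
  ceftriaxone: 2
  ciprofloxacin: 2
  clindamycin: 2
  gentamicin: 2
  metronidazole: 2
  piperacillin-tazobactam: 3
  ceftazidime: 3
  cefepime: 3
  vancomycin: 3
  tobramycin: 3
  meropenem: 4
  imipenem: 4
  linezolid: 4
  caspofungin: 4
synonyms:
  augmentin: amoxicillin-clavulanate
  co-amoxiclav: amoxicillin-clavulanate
  tazocin: piperacillin-tazobactam
  penicillin g: benzylpenicillin
# Selective digestive decontamination: routine prophylactic agents excluded
# from escalation detection within the listed post-admission windows.
sdd:
  drugs: [cefotaxime]
  days: [0, 1, 2, 3]
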