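# SOFA component cut-offs in AmsterdamUMCdb units (1996 consensus values).
# All cut-offs are data, not code: edit this file to change scoring behaviour.
respiration:
  unit: kPa
  # score s when PaO2/FiO2 falls below the s-th cut-off (400/300/200/100 mmHg)
  pf_cutoffs: [53.3, 40.0, 26.7, 13.3]
  # scores >= this value additionally require ventilatory support in the window
  ventilation_required_from: 3
coagulation:
  unit: 1e9/L
  platelet_cutoffs: [150.0, 100.0, 50.0, 20.0]
liver:
  unit: umol/L
  # lower bound of each score band (1.2/2.0/6.0/12.0 mg/dL)
  bilirubin_bounds: [20.0, 33.0, 102.0, 205.0]
cardiovascular:
  map_unit: mmHg
  hypotension_map: 70.0
  dose_unit: ug/kg/min
  dopamine_low: 5.0
  dopamine_high: 15.0
  norepinephrine_cutoff: 0.1
  # raw item name (after normalization) -> agent class used by the dose rules
  vasopressor_classes:
    dopamine: dopamine
    dobutamine: dobutamine
    norepinephrine: norepinephrine
    noradrenaline: norepinephrine
    epinephrine: epinephrine
    adrenaline: epinephrine
cns:
  # score s when GCS is strictly below the s-th cut-off
  gcs_cutoffs: [15, 13, 10, 6]
renal:
  creatinine_unit: umol/L
  # lower bound of each score band
  creatinine_bounds: [110.0, 171.0, 300.0, 441.0]
  urine_unit: mL/day
  urine_low: 500.0       # below -> at least score 3
  urine_very_low: 200.0  # below -> score 4
shock:
  cardiovascular_min_score: 3
  lactate_threshold: 2.0
  lactate_comparator: ge
  map_target: 65.0
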