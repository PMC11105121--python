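# Shipped outcome definitions.  Every code set and threshold here is
# configuration: edit or replace this file (or pass your own) to change the
# phenotyping rules without touching code.
#
# Comparators: ">=", ">", "<", "<=", "between" (value: [low, high], inclusive).
# "group" merges components that count as one criterion (e.g. systolic and
# diastolic pressure both count as the blood-pressure component).

t2d:
  onset_mean: 13.4
  combo: icd_and_support      # ICD code AND (medication OR qualifying lab)
  icd_codes: ["250.00", "250.02", "E11"]
  exclusion_icd: ["250.01", "250.03", "E10"]   # type-1-only patients excluded
  med_classes: [metformin, glipizide, glyburide, pioglitazone]
  lab_rules:
    - {analyte: fpg, op: ">=", value: 126, units: mg/dL}
    - {analyte: hba1c, op: ">=", value: 6.5, units: "%"}
    - {analyte: random_glucose, op: ">=", value: 200, units: mg/dL}

metabolic_syndrome:
  onset_mean: 12.5
  combo: any                  # ICD rule OR the IDF composite
  icd_codes: ["277.7", "E88.81"]
  idf:
    adiposity_bmi_percentile: 90   # waist >= 90th percentile proxied by BMI
    min_components: 2
    components:
      - {analyte: tg, op: ">=", value: 150, units: mg/dL}
      - {analyte: hdl, op: "<", value: 40, units: mg/dL}
      - {analyte: sbp, op: ">=", value: 130, units: mmHg, group: bp}
      - {analyte: dbp, op: ">=", value: 85, units: mmHg, group: bp}
      - {analyte: fpg, op: ">=", value: 100, units: mg/dL}

prediabetes:
  onset_mean: 12.3
  combo: any
  icd_codes: ["790.21", "790.22", "790.29", "R73.01", "R73.02", "R73.03", "R73.09", "R73.9"]
  lab_rules:
    - {analyte: fpg, op: between, value: [100, 125], units: mg/dL}
    - {analyte: hba1c, op: between, value: [5.7, 6.4], units: "%"}
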