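# Combined comorbidity score: condition weights after Gagne, Glynn, Avorn,
# Levin & Schneeweiss (2011), J Clin Epidemiol 64(7):749-759, which merges the
# Charlson (Romano adaptation) and Elixhauser condition sets into a single
# mortality-predictive integer score.  Diagnosis-code prefixes are ICD-9-CM
# (dots stripped), adapted from the Romano/Elixhauser definitions.  The file
# is data, not code: edit it to swap in Charlson weights or another coding
# system.
provenance: >
  Gagne JJ, Glynn RJ, Avorn J, Levin R, Schneeweiss S. A combined comorbidity
  score predicted mortality in elderly patients better than existing scores.
  J Clin Epidemiol. 2011;64(7):749-759. ICD-9-CM prefix mapping adapted from
  the Romano and Elixhauser condition definitions.
conditions:
  metastatic_cancer:
    weight: 5
    prefixes: ["196", "197", "198", "199"]
  congestive_heart_failure:
    weight: 2
    prefixes: ["39891", "428"]
  dementia:
    weight: 2
    prefixes: ["290", "2941", "3312"]
  renal_failure:
    weight: 2
    prefixes: ["585", "586", "V420", "V451", "V56"]
  weight_loss:
    weight: 2
    prefixes: ["260", "261", "262", "263"]
  hemiplegia:
    weight: 1
    prefixes: ["342", "344"]
  alcohol_abuse:
    weight: 1
    prefixes: ["291", "303", "3050"]
  any_tumor:
    weight: 1
    prefixes: ["14", "15", "16", "170", "171", "172", "174", "175",
               "179", "18", "190", "191", "192", "193", "194", "195"]
  cardiac_arrhythmia:
    weight: 1
    prefixes: ["426", "427"]
  chronic_pulmonary_disease:
    weight: 1
    prefixes: ["490", "491", "492", "493", "494", "495", "496"]
  coagulopathy:
    weight: 1
    prefixes: ["286", "2873", "2875"]
  complicated_diabetes:
    weight: 1
    prefixes: ["2504", "2505", "2506", "2507"]
  deficiency_anemia:
    weight: 1
    prefixes: ["280", "281"]
  fluid_electrolyte_disorder:
    weight: 1
    prefixes: ["276"]
  liver_disease:
    weight: 1
    prefixes: ["570", "571", "572"]
  peripheral_vascular_disease:
    weight: 1
    prefixes: ["440", "441", "4439", "7854", "V434"]
  psychosis:
    weight: 1
    prefixes: ["295", "297", "298"]
  pulmonary_circulation_disorder:
    weight: 1
    prefixes: ["415", "416", "417"]
  hiv_aids:
    weight: -1
    prefixes: ["042", "043", "044"]
  hypertension:
    weight: -1
    prefixes: ["401", "402", "403", "404", "405"]
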