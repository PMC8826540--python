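{
 "segments": [
  {
   "name": "ascending_aorta",
   "parent": null,
   "length_cm": 4.0,
   "area_prox_cm2": 5.3,
   "area_dist_cm2": 4.9,
   "distensibility_per_mmhg": 0.0052,
   "is_terminal": false
  },
  {
   "name": "aortic_arch_a",
   "parent": "ascending_aorta",
   "length_cm": 2.0,
   "area_prox_cm2": 3.8249999999999997,
   "area_dist_cm2": 3.57,
   "distensibility_per_mmhg": 0.0048,
   "is_terminal": false
  },
  {
   "name": "brachiocephalic",
   "parent": "ascending_aorta",
   "length_cm": 3.4,
   "area_prox_cm2": 1.4,
   "area_dist_cm2": 1.2,
   "distensibility_per_mmhg": 0.0032,
   "is_terminal": false
  },
  {
   "name": "aortic_arch_b",
   "parent": "aortic_arch_a",
   "length_cm": 3.9,
   "area_prox_cm2": 3.4849999999999994,
   "area_dist_cm2": 3.145,
   "distensibility_per_mmhg": 0.0048,
   "is_terminal": false
  },
  {
   "name": "l_carotid",
   "parent": "aortic_arch_a",
   "length_cm": 17.7,
   "area_prox_cm2": 0.55,
   "area_dist_cm2": 0.4,
   "distensibility_per_mmhg": 0.003,
   "is_terminal": true
  },
  {
   "name": "thoracic_aorta",
   "parent": "aortic_arch_b",
   "length_cm": 18.0,
   "area_prox_cm2": 3.06,
   "area_dist_cm2": 1.785,
   "distensibility_per_mmhg": 0.0042,
   "is_terminal": false
  },
  {
   "name": "l_subclavian",
   "parent": "aortic_arch_b",
   "length_cm": 3.4,
   "area_prox_cm2": 0.7,
   "area_dist_cm2": 0.6,
   "distensibility_per_mmhg": 0.0032,
   "is_terminal": false
  },
  {
   "name": "r_carotid",
   "parent": "brachiocephalic",
   "length_cm": 17.7,
   "area_prox_cm2": 0.55,
   "area_dist_cm2": 0.4,
   "distensibility_per_mmhg": 0.003,
   "is_terminal": true
  },
  {
   "name": "r_subclavian",
   "parent": "brachiocephalic",
   "length_cm": 3.4,
   "area_prox_cm2": 0.7,
   "area_dist_cm2": 0.6,
   "distensibility_per_mmhg": 0.0032,
   "is_terminal": false
  },
  {
   "name": "l_brachial",
   "parent": "l_subclavian",
   "length_cm": 20.0,
   "area_prox_cm2": 0.5,
   "area_dist_cm2": 0.32,
   "distensibility_per_mmhg": 0.0018,
   "is_terminal": true
  },
  {
   "name": "r_brachial",
   "parent": "r_subclavian",
   "length_cm": 20.0,
   "area_prox_cm2": 0.5,
   "area_dist_cm2": 0.32,
   "distensibility_per_mmhg": 0.0018,
   "is_terminal": true
  },
  {
   "name": "abdominal_aorta_a",
   "parent": "thoracic_aorta",
   "length_cm": 5.3,
   "area_prox_cm2": 1.785,
   "area_dist_cm2": 1.53,
   "distensibility_per_mmhg": 0.0034,
   "is_terminal": false
  },
  {
   "name": "celiac",
   "parent": "thoracic_aorta",
   "length_cm": 2.0,
   "area_prox_cm2": 0.9,
   "area_dist_cm2": 0.9,
   "distensibility_per_mmhg": 0.0024,
   "is_terminal": true
  },
  {
   "name": "abdominal_aorta_b",
   "parent": "abdominal_aorta_a",
   "length_cm": 2.0,
   "area_prox_cm2": 1.53,
   "area_dist_cm2": 1.4449999999999998,
   "distensibility_per_mmhg": 0.0034,
   "is_terminal": false
  },
  {
   "name": "sup_mesenteric",
   "parent": "abdominal_aorta_a",
   "length_cm": 3.0,
   "area_prox_cm2": 0.7,
   "area_dist_cm2": 0.7,
   "distensibility_per_mmhg": 0.0024,
   "is_terminal": true
  },
  {
   "name": "abdominal_aorta_c",
   "parent": "abdominal_aorta_b",
   "length_cm": 10.6,
   "area_prox_cm2": 1.36,
   "area_dist_cm2": 1.0625,
   "distensibility_per_mmhg": 0.0034,
   "is_terminal": false
  },
  {
   "name": "renal",
   "parent": "abdominal_aorta_b",
   "length_cm": 3.0,
   "area_prox_cm2": 1.2,
   "area_dist_cm2": 1.2,
   "distensibility_per_mmhg": 0.0024,
   "is_terminal": true
  },
  {
   "name": "l_iliac",
   "parent": "abdominal_aorta_c",
   "length_cm": 12.0,
   "area_prox_cm2": 0.95,
   "area_dist_cm2": 0.85,
   "distensibility_per_mmhg": 0.0024,
   "is_terminal": false
  },
  {
   "name": "r_iliac",
   "parent": "abdominal_aorta_c",
   "length_cm": 12.0,
   "area_prox_cm2": 0.95,
   "area_dist_cm2": 0.85,
   "distensibility_per_mmhg": 0.0024,
   "is_terminal": false
  },
  {
   "name": "l_femoral",
   "parent": "l_iliac",
   "length_cm": 25.0,
   "area_prox_cm2": 0.5,
   "area_dist_cm2": 0.45,
   "distensibility_per_mmhg": 0.0016,
   "is_terminal": true
  },
  {
   "name": "r_femoral",
   "parent": "r_iliac",
   "length_cm": 25.0,
   "area_prox_cm2": 0.5,
   "area_dist_cm2": 0.45,
   "distensibility_per_mmhg": 0.0016,
   "is_terminal": true
  }
 ],
 "terminals": [
  {
   "segment": "l_carotid",
   "r_char_mmhg_s_ml": 1.9305098950751598,
   "r_periph_mmhg_s_ml": 9.94449010492484,
   "c_term_ml_mmhg": 0.032
  },
  {
   "segment": "r_carotid",
   "r_char_mmhg_s_ml": 1.9305098950751598,
   "r_periph_mmhg_s_ml": 9.94449010492484,
   "c_term_ml_mmhg": 0.032
  },
  {
   "segment": "l_brachial",
   "r_char_mmhg_s_ml": 3.1153469472144675,
   "r_periph_mmhg_s_ml": 12.717986386118866,
   "c_term_ml_mmhg": 0.024
  },
  {
   "segment": "r_brachial",
   "r_char_mmhg_s_ml": 3.1153469472144675,
   "r_periph_mmhg_s_ml": 12.717986386118866,
   "c_term_ml_mmhg": 0.024
  },
  {
   "segment": "celiac",
   "r_char_mmhg_s_ml": 0.9592780792497876,
   "r_periph_mmhg_s_ml": 6.9573885874168795,
   "c_term_ml_mmhg": 0.048
  },
  {
   "segment": "sup_mesenteric",
   "r_char_mmhg_s_ml": 1.2333575304640125,
   "r_periph_mmhg_s_ml": 5.552356755250273,
   "c_term_ml_mmhg": 0.05600000000000001
  },
  {
   "segment": "renal",
   "r_char_mmhg_s_ml": 0.7194585594373406,
   "r_periph_mmhg_s_ml": 3.598723258744478,
   "c_term_ml_mmhg": 0.08800000000000001
  },
  {
   "segment": "l_femoral",
   "r_char_mmhg_s_ml": 2.349741815599103,
   "r_periph_mmhg_s_ml": 5.566924851067564,
   "c_term_ml_mmhg": 0.048
  },
  {
   "segment": "r_femoral",
   "r_char_mmhg_s_ml": 2.349741815599103,
   "r_periph_mmhg_s_ml": 5.566924851067564,
   "c_term_ml_mmhg": 0.048
  }
 ],
 "sites": {
  "carotid": {
   "segment": "l_carotid",
   "fraction": 0.8
  },
  "brachial": {
   "segment": "l_brachial",
   "fraction": 0.6
  },
  "femoral": {
   "segment": "r_femoral",
   "fraction": 0.2
  }
 },
 "blood_density_kg_m3": 1060.0,
 "blood_viscosity_mpa_s": 4.0,
 "reference_pressure_mmhg": 100.0,
 "reference_r_total_mmhg_s_ml": 0.9500000000000001,
 "reference_c_total_ml_mmhg": 1.0865033999999998,
 "reference_height_cm": 170.0,
 "reference_weight_kg": 70.0,
 "aging": {
  "ages": [
   18.0,
   25.0,
   75.0,
   90.0
  ],
  "proximal_factor": [
   1.0,
   1.0,
   0.7,
   0.6499999999999999
  ],
  "distal_aortic_factor": [
   1.0,
   1.0,
   0.8,
   0.75
  ],
  "proximal_segments": [
   "ascending_aorta",
   "aortic_arch_a",
   "aortic_arch_b"
  ],
  "distal_aortic_segments": [
   "thoracic_aorta",
   "abdominal_aorta_a",
   "abdominal_aorta_b",
   "abdominal_aorta_c"
  ]
 },
 "gender_area_offset": {
  "M": 0.0,
  "F": 0.0
 }
}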