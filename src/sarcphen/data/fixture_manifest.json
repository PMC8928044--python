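{
 "expected_marginals": {
  "n_patients": 200,
  "n_site_sf": 100,
  "n_site_pa": 100,
  "n_high": 158,
  "n_confirmed": 142,
  "n_probable": 16,
  "n_unlikely": 42,
  "table2": [
   [
    142,
    0
   ],
   [
    16,
    42
   ]
  ],
  "icd9_first_high": 108,
  "icd10_first_high": 50,
  "multi_organ_total": 60,
  "pulmonary_total": 143,
  "stage2_pulmonary": 47,
  "male_high": 142,
  "african_american_high": 85,
  "male_confirmed": 127,
  "female_confirmed": 15,
  "race_african_american_confirmed": 74,
  "race_non_hispanic_white_confirmed": 49,
  "race_hispanic_white_confirmed": 3,
  "race_unknown_confirmed": 12,
  "race_other_confirmed": 4,
  "icd9_confirmed": 98,
  "icd10_confirmed": 44,
  "organ_lung_only_confirmed": 86,
  "organ_multi_pulm_noncardiac_confirmed": 39,
  "organ_multi_pulm_cardiac_confirmed": 4,
  "organ_multi_cardiac_nonpulm_confirmed": 2,
  "organ_multi_neither_confirmed": 11,
  "organ_other_confirmed": 0,
  "pft_obstructive_confirmed": 27,
  "pft_restrictive_confirmed": 30,
  "pft_mixed_confirmed": 20,
  "pft_normal_confirmed": 39,
  "pft_missing_confirmed": 26,
  "scadding_stage0_confirmed": 22,
  "scadding_stage1_confirmed": 23,
  "scadding_stage2_confirmed": 45,
  "scadding_stage3_confirmed": 17,
  "scadding_stage4_confirmed": 22,
  "scadding_missing_confirmed": 13,
  "group_1_confirmed": 56,
  "group_2_confirmed": 6,
  "group_3_confirmed": 42,
  "group_5_confirmed": 17,
  "group_7_confirmed": 0,
  "group_8_confirmed": 30,
  "group_9_confirmed": 6,
  "age_mean_confirmed": 65.5,
  "age_sd_confirmed": 10.8,
  "male_probable": 15,
  "female_probable": 1,
  "race_african_american_probable": 11,
  "race_non_hispanic_white_probable": 3,
  "race_hispanic_white_probable": 0,
  "race_unknown_probable": 2,
  "race_other_probable": 0,
  "icd9_probable": 10,
  "icd10_probable": 6,
  "organ_lung_only_probable": 12,
  "organ_multi_pulm_noncardiac_probable": 2,
  "organ_multi_pulm_cardiac_probable": 0,
  "organ_multi_cardiac_nonpulm_probable": 0,
  "organ_multi_neither_probable": 2,
  "organ_other_probable": 0,
  "pft_obstructive_probable": 1,
  "pft_restrictive_probable": 6,
  "pft_mixed_probable": 5,
  "pft_normal_probable": 1,
  "pft_missing_probable": 3,
  "scadding_stage0_probable": 5,
  "scadding_stage1_probable": 3,
  "scadding_stage2_probable": 2,
  "scadding_stage3_probable": 4,
  "scadding_stage4_probable": 0,
  "scadding_missing_probable": 2,
  "group_1_probable": 4,
  "group_2_probable": 2,
  "group_3_probable": 3,
  "group_5_probable": 0,
  "group_7_probable": 0,
  "group_8_probable": 5,
  "group_9_probable": 0,
  "age_mean_probable": 69.3,
  "age_sd_probable": 10.3
 },
 "derived_marginals": {
  "group_4_confirmed": 20,
  "group_4_probable": 3,
  "group_6_confirmed": 5,
  "group_6_probable": 0
 },
 "checksum_sha256": "6d32787727cdce612ba48d669f2cfd9f7014633fefbba701aee3f606b4c72ff3"
}
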