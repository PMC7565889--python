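{
  "p_incomplete_ablation": 0.3,
  "sens_ct": 0.534,
  "spec_ct": 0.957,
  "sens_pet": 0.846,
  "spec_pet": 0.924,
  "cost_ct": 385.0,
  "cost_pet": 1375.0,
  "cost_ablation": 1493.0,
  "hospital_days": 4,
  "cost_hospital_day": 2184.0,
  "cost_reablation_total": 10229.0,
  "delayed_reablation_multiplier": 1.3,
  "cost_cancer_yearly": 25000.0,
  "cost_no_cancer_yearly": 0.0,
  "u_first_month": 0.95,
  "u_no_recurrence": 1.0,
  "u_hepatic_recurrence": 0.65,
  "u_other_recurrence": 0.19,
  "u_death": 0.0,
  "p_reablation_success": 0.93,
  "p_recurrence": 0.032,
  "p_mets_timely": 0.12,
  "p_mets_delayed": 0.15,
  "p_death_recurrence_yr": 0.0544,
  "p_remission_yr": 0.8,
  "discount_rate_yr": 0.03,
  "horizon_months": 24,
  "cycle_months": 1,
  "start_age_years": 68.0,
  "wtp": 100000.0
}
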