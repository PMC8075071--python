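# Default study conditions for the synthetic telemonitoring cohort.
# Any SimConfig field may be overridden here; unlisted fields keep
# their documented defaults.
n_patients: 29
seed: 0
age_mean: 67.4
age_sd: 8.0
prop_female: 0.45
fev1pp_mean: 45.5
fev1pp_sd: 17.7
ics_prob: 0.55
pre_exac_rate: 2.4            # exacerbations / person-year
hosp_days_per_severe_mean: 4.0
post_rate_ratio_exac: 0.310
post_rate_ratio_hospdays: 0.210
followup_median: 587.0        # days
followup_iqr: [372.0, 594.0]
mortality_prob: 0.10
adherence_prob: 0.43          # daily probability of answering
steps_baseline_mean: 2600.0
steps_baseline_sd: 1200.0
exac_step_decline: 0.35
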