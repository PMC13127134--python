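# Headline published projection results (values exactly as printed)
name,value,source
population_2025,23126258,results text: population aged 50+ in 2025
population_2040,24021710,results text: population aged 50+ in 2040
population_growth_pct,3.9,results text: population growth 2025-2040
frail_2025,16228687,results text: persons in any frailty state 2025
frail_2040,18269340,results text: persons in any frailty state 2040
frail_growth_pct,12.6,results text: frail count growth 2025-2040
prevalence_2025_pct,70.2,results text: frailty prevalence 2025
prevalence_2040_pct,76.1,results text: frailty prevalence 2040
total_new_cases,10006500,incidence table overall total
primary_frail_cost_rise_gbp_bn,1.6,results text: primary care frail cost rise (8.9 to 10.5 GBP bn)
secondary_frail_cost_rise_gbp_bn,8.4,results text: secondary care frail cost rise (36.8 to 45.2 GBP bn)
total_cost_increase_gbp_bn,10,results text: total health service cost increase 2025-2040
scenario_a_frail_2040,18073867,scenario results: frail count 2040 under scenario A
scenario_a_frail_delta_2040,195473,scenario results: baseline minus scenario A frail count 2040
scenario_a_gp_contact_reduction_millions,22,scenario results: ~22 million fewer GP appointments (A)
scenario_a_secondary_contact_reduction_millions,11.5,scenario results: 11.5 million fewer urgent and secondary contacts (A)
scenario_a_annual_saving_gbp_m,310,scenario results: scenario A saving per annum
scenario_a_cumulative_saving_gbp_bn,4.97,scenario results: scenario A cumulative saving over 16 years
scenario_b_modsev_2040,9021522,scenario results: moderate+severe count 2040 under scenario B
scenario_b_modsev_baseline_2040,9390865,scenario results: baseline moderate+severe count 2040
scenario_b_modsev_delta_2040,369343,scenario results: baseline minus scenario B moderate+severe 2040
scenario_b_gp_contact_reduction_millions,19.5,scenario results: ~19.5 million fewer GP appointments (B)
scenario_b_secondary_contact_reduction_millions,18.8,scenario results: 18.8 million fewer urgent and secondary contacts (B)
scenario_b_annual_saving_gbp_m,644,scenario results: scenario B saving per annum
scenario_b_cumulative_saving_gbp_bn,10.3,scenario results: scenario B cumulative saving over 16 years
scenario_c_unplanned_reduction_millions,2.48,scenario results: 2.48 million fewer unplanned admissions (C)
scenario_c_cumulative_saving_gbp_bn,4.2,scenario results: scenario C cumulative saving over 16 years
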