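demography:
  n_breeding_females_head: 100.0
  male_breeders_per_female: 0.105
  parturition_rate_per_female_year: 0.59
  prolificacy_lambs_per_parturition: 1.270398447737397
  sex_ratio_proportion_female_at_birth: 0.5
  lamb_mortality_risk: 0.2
  subadult_mortality_risk_female: 0.03834128797039859
  subadult_mortality_risk_male: 0.08216653948398175
  adult_mortality_risk_female: 0.040596465890286156
  adult_mortality_risk_male: 0.12752850036227795
  subadult_offtake_rate_female: 0.0395055768705093
  subadult_offtake_rate_male: 0.5396549548137818
  lamb_class_duration_years: 0.5
  subadult_class_duration_years: 0.5
prices:
  live_weight_kg:
    lamb: 10.278112547448734
    subadult_f: 18.08972954460335
    subadult_m: 18.08972954460335
    adult_f: 27.836928023729573
    adult_m: 29.836928023763146
  price_birr_per_head:
    lamb: 1225.5
    subadult_f: 1225.5
    subadult_m: 1526.7004615950493
    adult_f: 3336.622929966369
    adult_m: 6550.231714161835
  manure_output_kg_per_kg_liveweight_year: 10.0
  manure_price_birr_per_kg: 0.19478019307511601
  feed_dm_fraction_of_liveweight_per_day: 0.026
  exchange_rate_birr_per_usd: 43.0
  variable_cost_shares_of_revenue:
  - 0.15
  - 0.25
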