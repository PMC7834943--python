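variant,sex,term,coefficient
ckd_epi_2009,female,kappa,0.7
ckd_epi_2009,female,alpha,-0.329
ckd_epi_2009,female,sex_multiplier,1.018
ckd_epi_2009,male,kappa,0.9
ckd_epi_2009,male,alpha,-0.411
ckd_epi_2009,male,sex_multiplier,1.0
ckd_epi_2009,any,max_exponent,-1.209
ckd_epi_2009,any,age_base,0.993
ckd_epi_2009,any,scale,141
ckd_epi_2009,any,race_black_multiplier,1.159
framingham_lipid,female,ln_age,2.32888
framingham_lipid,female,ln_total_cholesterol,1.20904
framingham_lipid,female,ln_hdl_cholesterol,-0.70833
framingham_lipid,female,ln_sbp_untreated,2.76157
framingham_lipid,female,ln_sbp_treated,2.82263
framingham_lipid,female,smoker,0.52873
framingham_lipid,female,diabetes,0.69154
framingham_lipid,female,mean_linear_predictor,26.1931
framingham_lipid,female,baseline_survival,0.95012
framingham_lipid,male,ln_age,3.06117
framingham_lipid,male,ln_total_cholesterol,1.12370
framingham_lipid,male,ln_hdl_cholesterol,-0.93263
framingham_lipid,male,ln_sbp_untreated,1.93303
framingham_lipid,male,ln_sbp_treated,1.99881
framingham_lipid,male,smoker,0.65451
framingham_lipid,male,diabetes,0.57367
framingham_lipid,male,mean_linear_predictor,23.9802
framingham_lipid,male,baseline_survival,0.88936
framingham_bmi,female,ln_age,2.72107
framingham_bmi,female,ln_bmi,0.51125
framingham_bmi,female,ln_sbp_untreated,2.81291
framingham_bmi,female,ln_sbp_treated,2.88267
framingham_bmi,female,smoker,0.61868
framingham_bmi,female,diabetes,0.77763
framingham_bmi,female,mean_linear_predictor,26.0145
framingham_bmi,female,baseline_survival,0.94833
framingham_bmi,male,ln_age,3.11296
framingham_bmi,male,ln_bmi,0.79277
framingham_bmi,male,ln_sbp_untreated,1.85508
framingham_bmi,male,ln_sbp_treated,1.92672
framingham_bmi,male,smoker,0.70953
framingham_bmi,male,diabetes,0.53160
framingham_bmi,male,mean_linear_predictor,23.9388
framingham_bmi,male,baseline_survival,0.88431
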