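factor,category,is_reference,beta,se,mean_or_prop,points,points_hi,off_by_one
age,per_year,0,0.02,0.004,61.03,-2,8,0
gender,female,1,0.0,,0.53,0,,0
gender,male,0,-0.01,0.07,0.47,0,,0
onset_age,lt45,1,0.0,,0.20,0,,0
onset_age,ge45,0,-0.56,0.10,0.80,-6,,0
creatinine,lt2,1,0.0,,0.976,0,,0
creatinine,2to4,0,2.57,0.10,0.02,29,,0
creatinine,gt4,0,2.65,0.22,0.004,30,,0
hba1c_cv,low,1,0.0,,0.33,0,,0
hba1c_cv,mid,0,0.23,0.09,0.33,3,,0
hba1c_cv,high,0,0.48,0.09,0.34,6,,1
sbp_cv,low,1,0.0,,0.33,0,,0
sbp_cv,mid,0,-0.08,0.09,0.33,-1,,0
sbp_cv,high,0,0.24,0.09,0.34,3,,0
retinopathy,no,1,0.0,,0.99,0,,0
retinopathy,yes,0,0.88,0.17,0.01,10,,0
albuminuria,no,1,0.0,,0.88,0,,0
albuminuria,yes,0,0.50,0.09,0.12,6,,0
dm_med,none,1,0.0,,0.04,0,,0
dm_med,oral,0,-0.60,0.21,0.86,-7,,0
dm_med,insulin,0,0.45,0.23,0.04,5,,0
dm_med,insulin_oral,0,0.12,0.23,0.06,2,,1
bp_status,no_lt130,1,0.0,,0.20,0,,0
bp_status,no_130_139,0,0.12,0.21,0.14,1,,0
bp_status,no_140_159,0,0.46,0.20,0.12,5,,0
bp_status,no_ge160,0,0.72,0.25,0.03,8,,0
bp_status,yes_lt130,0,0.99,0.17,0.11,11,,0
bp_status,yes_130_139,0,1.06,0.17,0.13,12,,0
bp_status,yes_140_159,0,1.33,0.16,0.19,15,,0
bp_status,yes_ge160,0,1.65,0.17,0.08,19,,0
lipid_status,no_lt200,1,0.0,,0.39,0,,0
lipid_status,no_200_239,0,0.34,0.12,0.16,4,,0
lipid_status,no_ge240,0,0.53,0.17,0.04,6,,0
lipid_status,yes_lt200,0,0.36,0.11,0.17,4,,0
lipid_status,yes_200_239,0,0.35,0.11,0.15,4,,0
lipid_status,yes_ge240,0,0.91,0.11,0.09,10,,0
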