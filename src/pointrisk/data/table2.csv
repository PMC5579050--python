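stratification,category,n,events,person_years,rate,hr,hr_lo,hr_hi
age,30-34,133,2,1177,1.70,1.00,,
age,35-39,474,5,4246,1.18,0.69,0.13,3.55
age,40-44,1146,37,10136,3.65,2.14,0.52,8.89
age,45-49,2037,72,17898,4.02,2.37,0.58,9.65
age,50-54,3216,179,27923,6.41,3.78,0.94,15.24
age,55-59,3192,169,27315,6.19,3.65,0.90,14.70
age,60-64,4052,236,34158,6.91,4.05,1.01,16.29
age,65-69,3876,212,31760,6.68,3.95,0.98,15.90
age,70-74,3426,173,26540,6.52,3.97,0.99,16.02
age,75-79,1932,103,14026,7.34,4.61,1.14,18.66
age,80-84,620,27,3936,6.86,4.50,1.07,18.93
gender,female,12815,635,107541,5.90,1.00,,
gender,male,11289,580,91574,6.33,1.09,0.97,1.22
onset_age,lt45,4773,340,40570,8.38,1.00,,
onset_age,ge45,19331,875,158545,5.52,0.66,0.58,0.75
creatinine,lt2,23517,937,196164,4.78,1.00,,
creatinine,2to4,498,238,2479,96.01,24.54,21.25,28.34
creatinine,gt4,89,40,472,84.75,19.01,13.85,26.09
hba1c_cv,low,7828,324,65277,4.96,1.00,,
hba1c_cv,mid,8025,381,66902,5.69,1.45,1.26,1.68
hba1c_cv,high,8251,510,66936,7.62,1.70,1.47,1.96
sbp_cv,low,7948,349,65947,5.29,1.00,,
sbp_cv,mid,7958,357,66634,5.36,1.02,0.88,1.19
sbp_cv,high,8198,509,66535,7.65,1.48,1.29,1.69
retinopathy,no,23780,1154,196721,5.87,1.00,,
retinopathy,yes,324,61,2394,25.48,4.55,3.51,5.88
albuminuria,no,21211,974,176107,5.53,1.00,,
albuminuria,yes,2893,241,23008,10.47,1.91,1.66,2.20
dm_med,none,944,38,7476,5.08,1.00,,
dm_med,oral,20722,829,173596,4.78,0.91,0.65,1.25
dm_med,insulin,903,165,6244,26.43,5.16,3.63,7.35
dm_med,insulin_oral,1535,183,11799,15.51,3.02,2.13,4.28
bp_status,no_lt130,4661,83,39929,2.08,1.00,,
bp_status,no_130_139,3269,65,28074,2.32,1.10,0.79,1.52
bp_status,no_140_159,2904,88,24294,3.62,1.76,1.30,2.38
bp_status,no_ge160,726,29,5933,4.89,2.39,1.57,3.65
bp_status,yes_lt130,2735,154,22226,6.93,3.39,2.59,4.43
bp_status,yes_130_139,3125,211,25557,8.26,3.91,3.03,5.04
bp_status,yes_140_159,4605,359,36922,9.72,4.77,3.76,6.06
bp_status,yes_ge160,2079,226,16180,13.97,6.86,5.34,8.83
lipid_status,no_lt200,9706,299,80498,3.71,1.00,,
lipid_status,no_200_239,3738,163,31111,5.24,1.41,1.16,1.70
lipid_status,no_ge240,1006,72,8112,8.88,2.40,1.85,3.10
lipid_status,yes_lt200,3980,239,32698,7.31,1.93,1.63,2.29
lipid_status,yes_200_239,3493,208,29202,7.12,1.91,1.60,2.28
lipid_status,yes_ge240,2181,234,17496,13.37,3.62,3.05,4.29
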