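# SYNTHETIC Framingham-style primary-stroke coefficient set (10-year
# horizon). A plausible Cox-style reconstruction (age, SBP, diabetes,
# smoking, atrial fibrillation, LV hypertrophy, sex), centred so the base
# cohort profile sits at the reference risk 1 - S0 = 10%; NOT a
# transcription of a published equation. The engine multiplies this
# primary risk by the recurrent-vs-primary relative risk before use.
covariate,transform,coefficient
starting_age,identity,0.066
sbp,identity,0.015
diabetes_frac,indicator,0.52
smoker_frac,indicator,0.52
afib_frac,indicator,1.00
lvh_frac,indicator,0.80
male_frac,indicator,0.33
intercept,offset,-7.3752
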