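# SMART recurrent-cardiovascular-event risk score coefficients.
# 10-year composite risk = 1 - S0^exp(lp); S0 lives in the parameter file.
# Lipid coefficients are expressed per mg/dL (published per-mmol/L values
# divided by 38.67); hsCRP enters log-transformed (mg/L); the offset row is
# the published centring constant. History indicators: post_chd_weight ->
# coronary artery disease, post_stroke_weight -> cerebrovascular disease,
# aaa_history_frac -> abdominal aortic aneurysm, pad_history_frac ->
# peripheral arterial disease. These values are transcription data: correct
# them here, never in code.
covariate,transform,coefficient
starting_age,identity,-0.085
starting_age,square,0.00105
male_frac,indicator,0.156
smoker_frac,indicator,0.262
sbp,identity,0.00429
diabetes_frac,indicator,0.223
post_chd_weight,indicator,0.140
post_stroke_weight,indicator,0.406
aaa_history_frac,indicator,0.558
pad_history_frac,indicator,0.283
years_since_first_event,identity,0.0229
hdl,identity,-0.011016292
tc,identity,0.002479959
egfr,identity,-0.0532
egfr,square,0.000306
hscrp,log,0.139
intercept,offset,2.099
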