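# SYNTHETIC Framingham-style subsequent-CHD coefficient set (10-year
# horizon). A plausible reconstruction in the Framingham log-covariate
# style, calibrated to a realistic subsequent-CHD risk at the base cohort
# profile; NOT a transcription of a published equation. Used only by the
# two-equation scenario route. The offset row centres the linear predictor
# at the derivation-population mean.
covariate,transform,coefficient
starting_age,log,3.06117
tc,log,1.12370
hdl,log,-0.93263
sbp,log,1.93303
smoker_frac,indicator,0.65451
diabetes_frac,indicator,0.57367
intercept,offset,-23.9802
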