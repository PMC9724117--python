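# Pooled cohort atherosclerotic cardiovascular disease equations (2013),
# sex- and race-stratified Cox form: 10-year risk = 1 - S0^exp(L - mean_lp).
# Coefficients transcribed from the original 2013 guideline appendix and
# verified against its published reference profile (age 55, TC 213 mg/dL,
# HDL 50, untreated SBP 120, non-smoker, non-diabetic -> 2.1/3.0/5.3/6.1%
# for white female / black female / white male / black male).
stratum,variable,transform,coefficient,center,unit
white_female,ln_age,natural-log,-29.799,,years
white_female,ln_age_sq,natural-log-square,4.884,,years
white_female,ln_tc,natural-log,13.540,,mg/dL
white_female,ln_age_x_ln_tc,interaction,-3.114,,
white_female,ln_hdl,natural-log,-13.578,,mg/dL
white_female,ln_age_x_ln_hdl,interaction,3.149,,
white_female,ln_sbp_treated,natural-log,2.019,,mmHg
white_female,ln_sbp_untreated,natural-log,1.957,,mmHg
white_female,smoker,identity,7.574,,binary
white_female,ln_age_x_smoker,interaction,-1.665,,
white_female,diabetes,identity,0.661,,binary
black_female,ln_age,natural-log,17.114,,years
black_female,ln_tc,natural-log,0.940,,mg/dL
black_female,ln_hdl,natural-log,-18.920,,mg/dL
black_female,ln_age_x_ln_hdl,interaction,4.475,,
black_female,ln_sbp_treated,natural-log,29.291,,mmHg
black_female,ln_age_x_ln_sbp_treated,interaction,-6.432,,
black_female,ln_sbp_untreated,natural-log,27.820,,mmHg
black_female,ln_age_x_ln_sbp_untreated,interaction,-6.087,,
black_female,smoker,identity,0.691,,binary
black_female,diabetes,identity,0.874,,binary
white_male,ln_age,natural-log,12.344,,years
white_male,ln_tc,natural-log,11.853,,mg/dL
white_male,ln_age_x_ln_tc,interaction,-2.664,,
white_male,ln_hdl,natural-log,-7.990,,mg/dL
white_male,ln_age_x_ln_hdl,interaction,1.769,,
white_male,ln_sbp_treated,natural-log,1.797,,mmHg
white_male,ln_sbp_untreated,natural-log,1.764,,mmHg
white_male,smoker,identity,7.837,,binary
white_male,ln_age_x_smoker,interaction,-1.795,,
white_male,diabetes,identity,0.658,,binary
black_male,ln_age,natural-log,2.469,,years
black_male,ln_tc,natural-log,0.302,,mg/dL
black_male,ln_hdl,natural-log,-0.307,,mg/dL
black_male,ln_sbp_treated,natural-log,1.916,,mmHg
black_male,ln_sbp_untreated,natural-log,1.809,,mmHg
black_male,smoker,identity,0.549,,binary
black_male,diabetes,identity,0.645,,binary
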