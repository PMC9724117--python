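# Framingham general cardiovascular disease risk equation (2008), lipid-based
# variant, sex-stratified Cox form: 10-year risk = 1 - S0^exp(L - mean_lp).
# Coefficients transcribed from the original 2008 publication (verified
# against its worked example: woman, 61 y, TC 180 mg/dL, HDL 47, untreated
# SBP 124, smoker, non-diabetic -> 10.5%). Native lipid/SBP units: mg/dL and
# mmHg on the natural-log scale.
stratum,variable,transform,coefficient,center,unit
female,ln_age,natural-log,2.32888,,years
female,ln_tc,natural-log,1.20904,,mg/dL
female,ln_hdl,natural-log,-0.70833,,mg/dL
female,ln_sbp_untreated,natural-log,2.76157,,mmHg
female,ln_sbp_treated,natural-log,2.82263,,mmHg
female,smoker,identity,0.52873,,binary
female,diabetes,identity,0.69154,,binary
male,ln_age,natural-log,3.06117,,years
male,ln_tc,natural-log,1.12370,,mg/dL
male,ln_hdl,natural-log,-0.93263,,mg/dL
male,ln_sbp_untreated,natural-log,1.93303,,mmHg
male,ln_sbp_treated,natural-log,1.99881,,mmHg
male,smoker,identity,0.65451,,binary
male,diabetes,identity,0.57367,,binary
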