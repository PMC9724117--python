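# Framingham coronary heart disease risk equation (1998), risk-factor-category
# form, sex-stratified Cox form: 10-year risk = 1 - S0^exp(L - mean_lp).
# Coefficients transcribed from the original 1998 category-coefficient table.
# Cholesterol categories in mg/dL; blood-pressure category is the higher of
# the systolic and diastolic categories (JNC-V staging).
stratum,variable,transform,coefficient,center,unit
male,age,identity,0.04826,,years
male,tc_cat_lt160,indicator,-0.65945,,mg/dL
male,tc_cat_160_199,indicator,0.0,,mg/dL
male,tc_cat_200_239,indicator,0.17692,,mg/dL
male,tc_cat_240_279,indicator,0.50539,,mg/dL
male,tc_cat_ge280,indicator,0.65713,,mg/dL
male,hdl_cat_lt35,indicator,0.49744,,mg/dL
male,hdl_cat_35_44,indicator,0.24310,,mg/dL
male,hdl_cat_45_49,indicator,0.0,,mg/dL
male,hdl_cat_50_59,indicator,-0.05107,,mg/dL
male,hdl_cat_ge60,indicator,-0.48660,,mg/dL
male,bp_cat_optimal,indicator,-0.00226,,mmHg
male,bp_cat_normal,indicator,0.0,,mmHg
male,bp_cat_highnormal,indicator,0.28320,,mmHg
male,bp_cat_stage1,indicator,0.52168,,mmHg
male,bp_cat_stage2,indicator,0.61859,,mmHg
male,diabetes,identity,0.42839,,binary
male,smoker,identity,0.52337,,binary
female,age,identity,0.33766,,years
female,age_sq,square,-0.00268,,years^2
female,tc_cat_lt160,indicator,-0.26138,,mg/dL
female,tc_cat_160_199,indicator,0.0,,mg/dL
female,tc_cat_200_239,indicator,0.20771,,mg/dL
female,tc_cat_240_279,indicator,0.24385,,mg/dL
female,tc_cat_ge280,indicator,0.53513,,mg/dL
female,hdl_cat_lt35,indicator,0.84312,,mg/dL
female,hdl_cat_35_44,indicator,0.37796,,mg/dL
female,hdl_cat_45_49,indicator,0.19785,,mg/dL
female,hdl_cat_50_59,indicator,0.0,,mg/dL
female,hdl_cat_ge60,indicator,-0.42951,,mg/dL
female,bp_cat_optimal,indicator,-0.53363,,mmHg
female,bp_cat_normal,indicator,0.0,,mmHg
female,bp_cat_highnormal,indicator,-0.06773,,mmHg
female,bp_cat_stage1,indicator,0.26288,,mmHg
female,bp_cat_stage2,indicator,0.46573,,mmHg
female,diabetes,identity,0.59626,,binary
female,smoker,identity,0.29246,,binary
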