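# D:A:D 2010 HIV-specific 5-year CVD risk model, Poisson rate form:
# rate = baseline * exp(sum beta * (x - center)); 5-year risk =
# 1 - exp(-5 * rate). Log-coefficients derived from the adjusted
# incidence-rate ratios reported in the original 2010 publication; centering
# values from that study's published cohort characteristics; baseline rate
# from its crude CVD incidence (registry). Lipids in mmol/L, SBP per 10 mmHg,
# age per 5 years, protease-inhibitor exposures in years.
stratum,variable,transform,coefficient,center,unit
all,age_per5,identity,0.29267,8.0,5-years
all,male,identity,0.47000,0.74,binary
all,smoke_current,identity,0.58222,0.46,binary
all,smoke_ex,identity,0.30010,0.20,binary
all,family_history,identity,0.32208,0.09,binary
all,diabetes,identity,0.61519,0.04,binary
all,sbp_per10,identity,0.09531,12.0,10-mmHg
all,tc_mmol,identity,0.19885,5.2,mmol/L
all,hdl_mmol,identity,-0.59784,1.2,mmol/L
all,indinavir_years,identity,0.05827,1.0,years
all,lopinavir_years,identity,0.06766,0.6,years
all,abacavir_current,identity,0.36464,0.12,binary
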