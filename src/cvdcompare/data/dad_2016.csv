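# D:A:D 2016 (updated, full-model) HIV-specific 5-year CVD risk model,
# Poisson rate form: rate = baseline * exp(sum beta * (x - center));
# 5-year risk = 1 - exp(-5 * rate). The full model keeps the cumulative
# protease-inhibitor terms, current abacavir use, and the latest CD4 count
# (log2 scale, protective). Log-coefficients derived from the adjusted
# rate ratios reported in the 2016 update; centering at its development
# cohort's characteristics; baseline rate from its crude CVD incidence,
# whose broader endpoint set (including heart failure) makes it higher
# than the 2010 model's.
stratum,variable,transform,coefficient,center,unit
all,age_per5,identity,0.35066,7.8,5-years
all,male,identity,0.30010,0.735,binary
all,smoke_current,identity,0.53063,0.39,binary
all,smoke_ex,identity,0.23902,0.25,binary
all,family_history,identity,0.46373,0.08,binary
all,diabetes,identity,0.55962,0.03,binary
all,sbp_per10,identity,0.10436,12.1,10-mmHg
all,tc_mmol,identity,0.14842,5.0,mmol/L
all,hdl_mmol,identity,-0.77653,1.25,mmol/L
all,cd4_log2,natural-log2,-0.10536,8.97,log2(cells/mm^3)
all,indinavir_years,identity,0.04879,0.5,years
all,lopinavir_years,identity,0.07696,0.8,years
all,abacavir_current,identity,0.32208,0.11,binary
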