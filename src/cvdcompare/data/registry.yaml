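# Model registry: per-model coefficient file, functional form, horizon and
# stratum-level baseline constants.
#   cox  : risk = 1 - s0^exp(L - mean_lp)                (10-year models)
#   rate : risk = 1 - exp(-horizon * baseline * exp(L))  (5-year models)
# age_range is the development age range of each model; participants outside
# it are scored but flagged.
FHS_CVD:
  file: fhs_cvd_2008.csv
  form: cox
  horizon_years: 10
  stratum_by: sex
  age_range: [30, 74]
  strata:
    female: {s0: 0.95012, mean_lp: 26.1931}
    male: {s0: 0.88936, mean_lp: 23.9802}
FHS_CHD:
  file: fhs_chd_1998.csv
  form: cox
  horizon_years: 10
  stratum_by: sex
  age_range: [30, 74]
  strata:
    female: {s0: 0.96246, mean_lp: 9.92545}
    male: {s0: 0.90015, mean_lp: 3.0975}
ASCVD:
  file: ascvd_2013.csv
  form: cox
  horizon_years: 10
  stratum_by: sex_race
  age_range: [40, 79]
  strata:
    white_female: {s0: 0.9665, mean_lp: -29.18}
    black_female: {s0: 0.9533, mean_lp: 86.61}
    white_male: {s0: 0.9144, mean_lp: 61.18}
    black_male: {s0: 0.8954, mean_lp: 19.54}
DAD_2010:
  file: dad_2010.csv
  form: rate
  horizon_years: 5
  stratum_by: none
  age_range: [16, 85]
  strata:
    all: {baseline_rate: 0.0059}
DAD_2016:
  file: dad_2016.csv
  form: rate
  horizon_years: 5
  stratum_by: none
  age_range: [16, 85]
  strata:
    all: {baseline_rate: 0.0061}
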