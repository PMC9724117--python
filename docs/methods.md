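# Methods

## Scope and pipeline

The package reproduces a comparative risk-classification analysis: five CVD
risk equations applied to one HIV cohort, risks banded low/moderate/high,
and every model compared against the HIV-specific D:A:D 2010 reference by
cross-tabulation, percent agreement and Cohen's kappa. Stages: cohort
ingestion → phenotype derivation → eligibility (age 30–75 inclusive, no
established CVD) → blood-pressure multiple imputation → scoring →
categorization → agreement/subgroup summaries. All stages are pure
functions of (input, config, seed).

## Risk equations and their provenance

Coefficients are shipped as plain-text CSVs (`src/cvdcompare/data/`), one
file per model, each with a provenance header; the registry
(`registry.yaml`) holds functional form, horizon, stratum constants and
development age ranges. Nothing is refit or recalibrated.

* **FHS-CVD (2008, lipid variant)** and **ASCVD (2013)**: transcribed from
  the original publications and verified against their printed worked
  examples (the 61-year-old female profile → 10.48%; the age-55 reference
  profile → 2.1/3.0/5.3/6.1% across the four ASCVD sex×race strata). These
  agree with our engines to the printed rounding.
* **FHS-CHD (1998)**: the risk-factor-category form (JNC-V blood-pressure
  staging, cholesterol categories in mg/dL); the blood-pressure category is
  the higher of the systolic and diastolic stages.
* **D:A:D 2010/2016**: Poisson rate models. The digit-level published
  equation listings were not available during transcription, so the
  log-coefficients are derived from the publications' reported adjusted
  rate ratios, the centering values from the development cohorts' published
  characteristics, and the baseline rates from their crude CVD incidences
  (5.9 and 6.1 per 1000 person-years; the 2016 endpoint set is broader,
  which motivates its higher baseline). These files are therefore faithful
  in structure, sign and magnitude but approximate in the last digits;
  every engine is validated against an independent spreadsheet-style
  oracle that re-evaluates the same transcription with literal arithmetic.

Unit policy: the cohort layer is strictly mmol/L, mmHg, years, cells/mm³;
mg/dL conversion (× 38.67) happens inside scoring only.

ASCVD defaults to the African-American coefficient sets (the emulated study
population is Black African); `white` strata are available per record
(`race` column) or via configuration. The D:A:D 2016 default is the full
model (cumulative PI exposures, current abacavir, log₂ CD4); ex-smokers map
to the D:A:D ex-smoker term and to non-smoker for FHS/ASCVD. Participants
younger than a model's development floor (e.g. ASCVD, 40) are scored and
flagged, not dropped.

## Categorization and horizon

Bands: low < 10%, moderate 10–20% with both edges included (the interval
notation is read as closed; a documented convention, not a claim), high
> 20%. D:A:D risks are 5-year probabilities; by default they are
extrapolated to 10 years under a constant hazard, `p₁₀ = 1 − (1 − p₅)²`,
before banding (`dad_horizon: 5` keeps the native scale; both are exposed
because published practice is ambiguous between them).

## Imputation

Missingness is confined to SBP/DBP (the emulated design discards readings
from a non-validated device, ≈ 61.6%, assumed MAR). The imputer is a
chained-equations scheme with a Bayesian normal linear model per target:
σ² drawn from the scaled inverse-χ² posterior, β from its conditional
normal, and imputations with fresh residual noise; each of the m = 15
datasets is an independent chain of 10 sweeps in which each BP variable is
regressed on age, sex, BMI, smoking, total cholesterol, ART status and the
other BP variable. Predictive-mean matching (5 donors) is an option.
Observed cells are never modified; everything is reproducible from the
seed. Convergence is monitored by the per-sweep imputed-mean trace and
flagged (not failed) when the last-sweep drift exceeds 1%.

Downstream, risks are computed per imputed dataset and participants are
categorized on the mean of the m predicted probabilities (default); scalar
summaries can instead be pooled by Rubin's rules (point = mean, total
variance = within + (1 + 1/m)·between, classical degrees of freedom).

## Agreement statistics

Kappa is computed from the cross-tabulated counts with agreement weights
(identity/linear/quadratic); the null standard error is the classical
large-sample variance of weighted kappa, and p tests κ = 0. Interpretation
bands: ≤ 0.20 poor, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80
substantial, 0.81–1.00 almost perfect (applied to the 2-dp rounded value).
The **unweighted** scheme is the default: the published reference panels'
printed kappas (0.60/0.41/0.34/0.56) are reproduced exactly by unweighted
kappa on the printed counts (0.5998/0.4062/0.3417/0.5606), although the
source text calls them weighted; the discrepancy is documented rather than
silently resolved, and weighted schemes remain one switch away. Totals and
margins are always recomputed from cells — the reference D:A:D 2016 panel's
printed margins are internally inconsistent by 10 participants, and its
cells are taken as authoritative.

## Synthetic cohort generator

The generator emulates the published baseline table of a rural South
African HIV cohort. What is anchored to published numbers: sex split
(56.7% women); sex-specific means/SDs for age, BMI, SBP, DBP, total and HDL
cholesterol; sex-specific current smoking (42.8%/8.2%) and family history
(13.5%/20.1%); diabetes (3.5%), BP treatment (3.5%), ART coverage (86.7%),
abacavir use among ART (2.5%); CD4 lognormal matched to the published
median 469 with σ from the IQR ratio (a lognormal cannot also hit the
slightly skewed printed quartiles exactly). What is invented and so
labelled: the joint dependence structure (Gaussian copula with rank
correlations age–SBP 0.30, age–TC 0.20, BMI–SBP 0.25, SBP–DBP 0.70, …),
ex-smoker prevalence (10%), PI-exposure distributions (zero-inflated
exponentials), and established-CVD prevalence (2%, to exercise the
eligibility filter). Truncated-normal marginals are moment-matched
numerically so that truncation (e.g. age to [30, 75]) does not bias the
configured means. HDL < total cholesterol is enforced by resampling
violators from the admissible quantile range.

Missingness injection hits the target fraction exactly (weighted sampling
without replacement via Gumbel top-k); under MAR the selection log-odds are
linear in age (0.03/y) and sex (+0.2 for women).

Because only marginals are anchored, passing distributional tests shows the
pipeline behaves correctly under realistic inputs — not that the synthetic
cohort equals the real one. In particular the real cohort's exact category
counts are not reproducible; the suite instead asserts the qualitative
structure the analysis reported (predominantly low-risk cohort, the D:A:D
2016 model flagging the largest high-risk fraction, high-risk share rising
with age).

## Numerical conventions and edge cases

* Analysis BP is the mean of readings 2 and 3; with exactly two readings it
  degenerates to reading 2; fewer than two leaves BP missing (routed to
  imputation, not an error). Diabetes: HbA1c strictly > 6.5 (configurable)
  or medication.
* Blank booleans in input files (e.g. unanswered established-CVD
  questions) default to False and are counted in the parse report;
  unparseable numeric cells become nulls and are counted likewise.
* Display rounding is one decimal for percents and two for kappa; full
  precision is kept internally. Kappa with Pe = 1 raises a distinct
  undefined-kappa error, never returns 0.
* Monotonicity of the equations holds "per the published tables", which
  implies documented exceptions: the pooled-cohort ln(age) interactions
  reverse the HDL effect above ~69 y (African-American women) / ~75 y
  (white women) and make age locally non-monotone for younger white women
  with adverse lipids; the 1998 Framingham women's age² term peaks at
  ~63 y; property tests sample the sign-determinate domains.
* Problem sizes used by the test suite and acceptance script — n = 2000
  (imputation recovery), 5000 (MCAR bias), 10 000 (cohort-level
  properties), 100 000 (marginal convergence) — are the package's chosen
  simulation scales, balancing Monte-Carlo error against quick iteration.

## Known limitations

* The D:A:D coefficient files are rate-ratio-derived approximations (see
  provenance above); absolute D:A:D risks should be treated as indicative.
* No outcome data exist anywhere in the pipeline, so no calibration,
  discrimination or net-reclassification statistics are offered.
* Imputation covers blood pressure only; other variables are assumed
  complete (the generator guarantees this), and MNAR mechanisms are out of
  scope.
* The generator's SBP spread uses the published validated-device subset SD
  for everyone and may understate population spread.
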