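"""Scoring engines: transcription fidelity, functional-form identities,
categorization and horizon extrapolation."""

import copy

import numpy as np
import pytest

import oracles
from conftest import make_record
from cvdcompare.risk_models import (
    ModelID,
    RiskCategory,
    ScoringError,
    categorize_risk,
    extrapolate_risk,
    load_coefficients,
    score_cox_form,
    score_dad,
    score_frame,
)

# five hand-built profiles per stratum: (age, tc mmol/L, hdl mmol/L, sbp,
# treated, smoker, diabetic)
PROFILES = [
    (55.0, 5.51, 1.29, 120.0, False, False, False),
    (43.0, 4.30, 1.40, 115.0, False, True, False),
    (62.0, 6.50, 0.90, 150.0, True, False, True),
    (35.0, 3.80, 1.80, 105.0, False, False, False),
    (70.0, 5.00, 1.10, 165.0, True, True, True),
]


def _record_from_profile(sex, profile, race="black", smoking_override=None):
    age, tc, hdl, sbp, treated, smoker, diabetic = profile
    return make_record(
        age=age, sex=sex, total_chol=tc, hdl_chol=hdl, sbp=sbp, dbp=0.6 * sbp,
        bp_treated=treated, smoking=smoking_override or ("current" if smoker else "never"),
        diabetes=diabetic, race=race,
    )


class TestTranscriptionAgainstIndependentOracle:
    @pytest.mark.parametrize("sex", ["male", "female"])
    @pytest.mark.parametrize("profile", PROFILES)
    def test_fhs_cvd(self, sex, profile):
        rec = _record_from_profile(sex, profile)
        expected = oracles.fhs_cvd_oracle(sex, profile[0], profile[1], profile[2],
                                          profile[3], profile[4], profile[5], profile[6])
        assert score_cox_form(rec, "FHS_CVD").probability == pytest.approx(
            expected, abs=1e-10)

    @pytest.mark.parametrize("sex", ["male", "female"])
    @pytest.mark.parametrize("profile", PROFILES)
    def test_fhs_chd(self, sex, profile):
        rec = _record_from_profile(sex, profile)
        expected = oracles.fhs_chd_oracle(
            sex, profile[0], profile[1], profile[2],
            profile[3], 0.6 * profile[3], profile[5], profile[6])
        assert score_cox_form(rec, "FHS_CHD").probability == pytest.approx(
            expected, abs=1e-10)

    @pytest.mark.parametrize("stratum", ["white_female", "black_female",
                                         "white_male", "black_male"])
    @pytest.mark.parametrize("profile", PROFILES)
    def test_ascvd(self, stratum, profile):
        race, sex = stratum.split("_")
        rec = _record_from_profile(sex, profile, race=race)
        expected = oracles.ascvd_oracle(stratum, profile[0], profile[1], profile[2],
                                        profile[3], profile[4], profile[5], profile[6])
        assert score_cox_form(rec, "ASCVD").probability == pytest.approx(
            expected, abs=1e-10)

    @pytest.mark.parametrize("version", [2010, 2016])
    @pytest.mark.parametrize("profile", PROFILES)
    @pytest.mark.parametrize("smoking", ["never", "ex", "current"])
    def test_dad(self, version, profile, smoking):
        rec = _record_from_profile("male", profile, smoking_override=smoking)
        expected = oracles.dad_oracle(
            version, profile[0], True, smoking, rec.family_history_cvd, profile[6],
            profile[3], profile[1], profile[2],
            rec.exposure_years_pi_indinavir, rec.exposure_years_pi_lopinavir,
            rec.abacavir_current, cd4=rec.cd4_latest)
        assert score_dad(rec, version=version).probability == pytest.approx(
            expected, abs=1e-10)

    def test_published_reference_profiles(self):
        """Worked examples printed with the original equations."""
        woman = make_record(age=61, sex="female", total_chol=180 / 38.67,
                            hdl_chol=47 / 38.67, sbp=124, dbp=70, bp_treated=False,
                            smoking="current")
        assert 100 * score_cox_form(woman, "FHS_CVD").probability == pytest.approx(
            10.48, abs=0.05)
        ref = dict(total_chol=213 / 38.67, hdl_chol=50 / 38.67, sbp=120, dbp=70,
                   bp_treated=False, smoking="never", age=55)
        printed = {"white_female": 2.1, "black_female": 3.0,
                   "white_male": 5.3, "black_male": 6.1}
        for stratum, pct in printed.items():
            race, sex = stratum.split("_")
            rec = make_record(sex=sex, race=race, **ref)
            assert 100 * score_cox_form(rec, "ASCVD").probability == pytest.approx(
                pct, abs=0.1)


class TestFunctionalFormIdentities:
    @pytest.mark.parametrize("model", ["FHS_CVD", "FHS_CHD", "ASCVD"])
    def test_cox_zero_coefficient_limit_is_one_minus_s0(self, model, record):
        coeffs = copy.deepcopy(load_coefficients(model))
        for s in coeffs.strata.values():
            s.terms = [t.__class__(t.variable, t.transform, 0.0, t.center, t.unit)
                       for t in s.terms]
            s.mean_lp = 0.0
        est = score_cox_form(record, coeffs)
        key = "male" if "male" in coeffs.strata else "black_male"
        s0 = coeffs.strata[key].s0
        assert est.probability == pytest.approx(1.0 - s0, abs=0.0)

    @pytest.mark.parametrize("model,version", [("DAD_2010", 2010), ("DAD_2016", 2016)])
    def test_rate_zero_coefficient_limit(self, model, version, record):
        coeffs = copy.deepcopy(load_coefficients(model))
        for s in coeffs.strata.values():
            s.terms = [t.__class__(t.variable, t.transform, 0.0, t.center, t.unit)
                       for t in s.terms]
        est = score_dad(record, coeffs, version=version)
        lam = coeffs.strata["all"].baseline_rate
        assert est.probability == pytest.approx(1.0 - np.exp(-5.0 * lam), abs=0.0)

    def test_rate_form_at_centering_means_returns_baseline_risk(self):
        coeffs = load_coefficients("DAD_2010")
        centers = {t.variable: t.center for t in coeffs.strata["all"].terms}
        rec = make_record(
            age=5 * centers["age_per5"], sex="male", smoking="never",
            diabetes=False, family_history_cvd=False,
            sbp=10 * centers["sbp_per10"], dbp=80,
            total_chol=centers["tc_mmol"], hdl_chol=centers["hdl_mmol"],
            exposure_years_pi_indinavir=centers["indinavir_years"],
            exposure_years_pi_lopinavir=centers["lopinavir_years"],
        )
        est = score_dad(rec, version=2010)
        # non-centered binaries (male=1 vs 0.74 etc.) contribute; undo by hand
        resid = (0.47 * (1 - 0.74) - 0.58222 * 0.46 - 0.3001 * 0.20
                 - 0.32208 * 0.09 - 0.61519 * 0.04 - 0.36464 * 0.12)
        lam = 0.0059 * np.exp(resid)
        assert est.probability == pytest.approx(1 - np.exp(-5 * lam), rel=1e-12)

    def test_scoring_is_pure(self, record):
        a = score_cox_form(record, "FHS_CVD").probability
        b = score_cox_form(record, "FHS_CVD").probability
        assert a == b


class TestErrors:
    def test_null_required_variable_names_variable_and_model(self):
        rec = make_record(sbp=None, dbp=None)
        with pytest.raises(ScoringError, match="FHS_CVD.*sbp"):
            score_cox_form(rec, "FHS_CVD")

    def test_dad_2016_requires_cd4(self):
        rec = make_record(cd4_latest=None)
        with pytest.raises(ScoringError, match="cd4"):
            score_dad(rec, version=2016)

    def test_negative_exposure_years_rejected(self):
        # bypass the dataclass guard by editing the frame directly
        import conftest
        df = conftest.make_frame(3, seed=2)
        df.loc[0, "exposure_years_pi_indinavir"] = -0.5
        with pytest.raises(ScoringError, match="negative"):
            score_frame(df, load_coefficients("DAD_2010"))

    def test_out_of_development_age_range_flagged_not_rejected(self):
        rec = make_record(age=32)
        est = score_cox_form(rec, "ASCVD")  # development floor is 40
        assert est.age_out_of_range and 0 < est.probability < 1


class TestCategorization:
    @pytest.mark.parametrize("p,expected", [
        (0.05, RiskCategory.LOW),
        (0.0999999, RiskCategory.LOW),
        (0.10, RiskCategory.MODERATE),
        (0.15, RiskCategory.MODERATE),
        (0.20, RiskCategory.MODERATE),
        (0.2000001, RiskCategory.HIGH),
        (0.0, RiskCategory.LOW),
        (1.0, RiskCategory.HIGH),
    ])
    def test_band_boundaries(self, p, expected):
        assert categorize_risk(p) is expected

    @pytest.mark.parametrize("p", [-0.01, 1.01, float("nan")])
    def test_domain_errors(self, p):
        with pytest.raises(ScoringError):
            categorize_risk(p)


class TestExtrapolation:
    def test_closed_form_value(self, record):
        est = score_dad(record, version=2010)
        est = est.__class__(est.model_id, 5.0, 0.10, RiskCategory.MODERATE)
        out = extrapolate_risk(est, 10)
        assert out.probability == pytest.approx(1 - 0.81, rel=1e-12)
        assert out.extrapolated and out.horizon_years == 10

    def test_zero_is_fixed_point(self, record):
        est = score_dad(record, version=2010)
        est = est.__class__(est.model_id, 5.0, 0.0, RiskCategory.LOW)
        assert extrapolate_risk(est, 10).probability == 0.0

    def test_algebraic_bounds_hold(self):
        rng = np.random.default_rng(11)
        for p in rng.uniform(0, 0.9, 200):
            est = extrapolate_risk(
                score_dad(make_record(), version=2010).__class__(
                    ModelID.DAD_2010, 5.0, p, categorize_risk(min(p, 1.0))), 10)
            assert p <= est.probability <= min(2 * p, 1.0) + 1e-12

    def test_shorter_target_rejected(self):
        est = score_dad(make_record(), version=2010)
        with pytest.raises(ScoringError):
            extrapolate_risk(est, 2)
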