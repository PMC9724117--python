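"""Independent oracles for the test suite.

Each scoring oracle re-evaluates a risk equation with literal published
constants and explicit arithmetic, bypassing the package's coefficient
files, feature registry and vectorized engine entirely, so an agreement
between the two routes validates both the transcription and the plumbing.
The kappa oracle uses exact rational arithmetic over an explicit double
loop.
"""

from __future__ import annotations

import math
from fractions import Fraction

MGDL = 38.67


def fhs_cvd_oracle(sex, age, tc_mmol, hdl_mmol, sbp, treated, smoker, diabetic):
    """Framingham general-CVD 2008, lipid variant, 10-year risk."""
    tc, hdl = tc_mmol * MGDL, hdl_mmol * MGDL
    if sex == "female":
        lp = (2.32888 * math.log(age) + 1.20904 * math.log(tc)
              - 0.70833 * math.log(hdl)
              + (2.82263 if treated else 2.76157) * math.log(sbp)
              + 0.52873 * smoker + 0.69154 * diabetic)
        return 1.0 - 0.95012 ** math.exp(lp - 26.1931)
    lp = (3.06117 * math.log(age) + 1.12370 * math.log(tc)
          - 0.93263 * math.log(hdl)
          + (1.99881 if treated else 1.93303) * math.log(sbp)
          + 0.65451 * smoker + 0.57367 * diabetic)
    return 1.0 - 0.88936 ** math.exp(lp - 23.9802)


def _chd_tc_coef(sex, tc):
    male = [(-0.65945, 160), (0.0, 200), (0.17692, 240), (0.50539, 280), (0.65713, None)]
    female = [(-0.26138, 160), (0.0, 200), (0.20771, 240), (0.24385, 280), (0.53513, None)]
    for coef, hi in (male if sex == "male" else female):
        if hi is None or tc < hi:
            return coef


def _chd_hdl_coef(sex, hdl):
    male = [(0.49744, 35), (0.24310, 45), (0.0, 50), (-0.05107, 60), (-0.48660, None)]
    female = [(0.84312, 35), (0.37796, 45), (0.19785, 50), (0.0, 60), (-0.42951, None)]
    for coef, hi in (male if sex == "male" else female):
        if hi is None or hdl < hi:
            return coef


def _chd_bp_coef(sex, sbp, dbp):
    stage_s = 0 if sbp < 120 else 1 if sbp < 130 else 2 if sbp < 140 else 3 if sbp < 160 else 4
    stage_d = 0 if dbp < 80 else 1 if dbp < 85 else 2 if dbp < 90 else 3 if dbp < 100 else 4
    stage = max(stage_s, stage_d)
    male = [-0.00226, 0.0, 0.28320, 0.52168, 0.61859]
    female = [-0.53363, 0.0, -0.06773, 0.26288, 0.46573]
    return (male if sex == "male" else female)[stage]


def fhs_chd_oracle(sex, age, tc_mmol, hdl_mmol, sbp, dbp, smoker, diabetic):
    """Framingham CHD 1998, risk-factor-category form, 10-year risk."""
    tc, hdl = tc_mmol * MGDL, hdl_mmol * MGDL
    if sex == "male":
        lp = (0.04826 * age + _chd_tc_coef(sex, tc) + _chd_hdl_coef(sex, hdl)
              + _chd_bp_coef(sex, sbp, dbp) + 0.42839 * diabetic + 0.52337 * smoker)
        return 1.0 - 0.90015 ** math.exp(lp - 3.0975)
    lp = (0.33766 * age - 0.00268 * age**2 + _chd_tc_coef(sex, tc)
          + _chd_hdl_coef(sex, hdl) + _chd_bp_coef(sex, sbp, dbp)
          + 0.59626 * diabetic + 0.29246 * smoker)
    return 1.0 - 0.96246 ** math.exp(lp - 9.92545)


def ascvd_oracle(stratum, age, tc_mmol, hdl_mmol, sbp, treated, smoker, diabetic):
    """Pooled-cohort ASCVD 2013 10-year risk; stratum e.g. 'black_female'."""
    la, lt, lh, ls = (math.log(age), math.log(tc_mmol * MGDL),
                      math.log(hdl_mmol * MGDL), math.log(sbp))
    if stratum == "white_female":
        lp = (-29.799 * la + 4.884 * la**2 + 13.540 * lt - 3.114 * la * lt
              - 13.578 * lh + 3.149 * la * lh
              + (2.019 if treated else 1.957) * ls
              + 7.574 * smoker - 1.665 * la * smoker + 0.661 * diabetic)
        s0, mean = 0.9665, -29.18
    elif stratum == "black_female":
        lp = (17.114 * la + 0.940 * lt - 18.920 * lh + 4.475 * la * lh
              + ((29.291 * ls - 6.432 * la * ls) if treated
                 else (27.820 * ls - 6.087 * la * ls))
              + 0.691 * smoker + 0.874 * diabetic)
        s0, mean = 0.9533, 86.61
    elif stratum == "white_male":
        lp = (12.344 * la + 11.853 * lt - 2.664 * la * lt
              - 7.990 * lh + 1.769 * la * lh
              + (1.797 if treated else 1.764) * ls
              + 7.837 * smoker - 1.795 * la * smoker + 0.658 * diabetic)
        s0, mean = 0.9144, 61.18
    elif stratum == "black_male":
        lp = (2.469 * la + 0.302 * lt - 0.307 * lh
              + (1.916 if treated else 1.809) * ls
              + 0.549 * smoker + 0.645 * diabetic)
        s0, mean = 0.8954, 19.54
    else:
        raise ValueError(stratum)
    return 1.0 - s0 ** math.exp(lp - mean)


def dad_oracle(version, age, male, smoking, famhist, diabetic, sbp, tc_mmol,
               hdl_mmol, idv_years, lpv_years, abacavir, cd4=None):
    """D:A:D 5-year CVD risk, rate form with centered covariates."""
    cur, ex = smoking == "current", smoking == "ex"
    if version == 2010:
        lp = (0.29267 * (age / 5 - 8.0) + 0.47000 * (male - 0.74)
              + 0.58222 * (cur - 0.46) + 0.30010 * (ex - 0.20)
              + 0.32208 * (famhist - 0.09) + 0.61519 * (diabetic - 0.04)
              + 0.09531 * (sbp / 10 - 12.0) + 0.19885 * (tc_mmol - 5.2)
              - 0.59784 * (hdl_mmol - 1.2) + 0.05827 * (idv_years - 1.0)
              + 0.06766 * (lpv_years - 0.6) + 0.36464 * (abacavir - 0.12))
        baseline = 0.0059
    else:
        lp = (0.35066 * (age / 5 - 7.8) + 0.30010 * (male - 0.735)
              + 0.53063 * (cur - 0.39) + 0.23902 * (ex - 0.25)
              + 0.46373 * (famhist - 0.08) + 0.55962 * (diabetic - 0.03)
              + 0.10436 * (sbp / 10 - 12.1) + 0.14842 * (tc_mmol - 5.0)
              - 0.77653 * (hdl_mmol - 1.25) - 0.10536 * (math.log2(cd4) - 8.97)
              + 0.04879 * (idv_years - 0.5) + 0.07696 * (lpv_years - 0.8)
              + 0.32208 * (abacavir - 0.11))
        baseline = 0.0061
    return 1.0 - math.exp(-5.0 * baseline * math.exp(lp))


def kappa_oracle(counts, scheme="unweighted") -> Fraction:
    """Exact rational (weighted) Cohen's kappa via an explicit double loop."""
    k = len(counts)
    n = sum(sum(row) for row in counts)
    row = [Fraction(sum(counts[i][j] for j in range(k)), n) for i in range(k)]
    col = [Fraction(sum(counts[i][j] for i in range(k)), n) for j in range(k)]

    def w(i, j):
        d = Fraction(abs(i - j), k - 1)
        if scheme == "unweighted":
            return Fraction(1 if i == j else 0)
        if scheme == "linear":
            return 1 - d
        return 1 - d * d

    po = Fraction(0)
    pe = Fraction(0)
    for i in range(k):
        for j in range(k):
            po += w(i, j) * Fraction(counts[i][j], n)
            pe += w(i, j) * row[i] * col[j]
    if pe == 1:
        raise ZeroDivisionError("kappa undefined")
    return (po - pe) / (1 - pe)
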