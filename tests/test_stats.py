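"""Reliability statistics and the repeated-measures ANOVA battery."""
import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from choroquant import (
    RepeatPairs,
    bland_altman,
    bonferroni_pairwise,
    coefficient_of_repeatability,
    icc_agreement,
    rm_anova,
    within_subject_sd,
)
from choroquant.stats import significance_stars


def test_within_subject_sd_closed_forms():
    same = RepeatPairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert within_subject_sd(same) == 0.0
    unit = RepeatPairs([1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0])  # |d| = 1
    assert within_subject_sd(unit) == pytest.approx(1 / np.sqrt(2))
    assert coefficient_of_repeatability(unit) == pytest.approx(1.96)


def test_cor_sw_identity_random_data():
    rng = np.random.default_rng(0)
    pairs = RepeatPairs(rng.normal(10, 2, 15), rng.normal(10, 2, 15))
    sw = within_subject_sd(pairs)
    assert coefficient_of_repeatability(pairs) == pytest.approx(
        2.771859 * sw, rel=1e-5
    )
    assert coefficient_of_repeatability(pairs) == pytest.approx(
        1.96 * np.sqrt(2) * sw, rel=1e-12
    )


def test_icc_perfect_agreement():
    pairs = RepeatPairs([10, 20, 30, 40.0], [10, 20, 30, 40.0])
    assert icc_agreement(pairs) == pytest.approx(1.0)


def test_icc_worked_table_against_mean_squares_oracle():
    m1 = np.array([10, 20, 30, 40, 50.0])
    m2 = np.array([12, 19, 33, 38, 51.0])
    x = np.column_stack([m1, m2])
    n, k = x.shape
    grand = x.mean()
    ms_r = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
    ms_e = (((x - grand) ** 2).sum()
            - (n - 1) * ms_r - (k - 1) * ms_c) / ((n - 1) * (k - 1))
    expect = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))
    assert icc_agreement(RepeatPairs(m1, m2)) == pytest.approx(expect, rel=1e-12)


def test_icc_matches_pingouin_icc2():
    rng = np.random.default_rng(7)
    subj = rng.normal(50, 10, 12)
    m1 = subj + rng.normal(0, 2, 12)
    m2 = subj + rng.normal(0, 2, 12)
    ours = icc_agreement(RepeatPairs(m1, m2))
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(12), 2),
        "rater": np.tile([0, 1], 12),
        "score": np.column_stack([m1, m2]).ravel(),
    })
    ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                             ratings="score")
    icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
    assert ours == pytest.approx(icc2, abs=1e-6)


def test_icc_penalises_constant_offset():
    rng = np.random.default_rng(3)
    m1 = rng.normal(30, 5, 10)
    m2 = m1 + rng.normal(0, 0.5, 10)
    biased = icc_agreement(RepeatPairs(m1, m2 + 3.0))
    unbiased = icc_agreement(RepeatPairs(m1, m2))
    assert biased < unbiased


def test_bland_altman_closed_forms():
    same = bland_altman(RepeatPairs([1.0, 2.0], [1.0, 2.0]))
    assert same.ba_mean_diff == 0.0
    assert same.ba_loa_low == same.ba_loa_high == 0.0

    # differences {-1, +1}: sample SD = sqrt(2), LoA = ±1.96*sqrt(2)
    ba = bland_altman(RepeatPairs([0.0, 1.0], [1.0, 0.0]))
    assert ba.ba_mean_diff == 0.0
    assert ba.ba_loa_high == pytest.approx(1.96 * np.sqrt(2))
    assert ba.ba_loa_low == pytest.approx(-1.96 * np.sqrt(2))


def test_bland_altman_matches_direct_formulas():
    rng = np.random.default_rng(11)
    a, b = rng.normal(5, 1, 20), rng.normal(5, 1, 20)
    ba = bland_altman(RepeatPairs(a, b))
    d = a - b
    from scipy.stats import t as tdist

    assert ba.ba_mean_diff == pytest.approx(d.mean())
    assert ba.ba_loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
    half = tdist.ppf(0.975, 19) * d.std(ddof=1) / np.sqrt(20)
    assert ba.ba_ci_high == pytest.approx(d.mean() + half)


def test_rm_anova_degenerate_table():
    x = np.tile([[3.0], [5.0], [9.0]], (1, 4))  # no level effect, no error
    res = rm_anova(x)
    assert res.f_stat == 0.0 and res.p_value == 1.0
    assert res.df_num == 3 and res.df_den == 6


def test_rm_anova_worked_table_against_sums_of_squares():
    x = np.array([[3.0, 4.0, 6.0],
                  [5.0, 6.0, 9.0],
                  [2.0, 2.0, 5.0],
                  [7.0, 9.0, 12.0]])
    n, k = x.shape
    grand = x.mean()
    ss_treat = n * ((x.mean(0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(1) - grand) ** 2).sum()
    ss_err = ((x - grand) ** 2).sum() - ss_treat - ss_subj
    f_expect = (ss_treat / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    res = rm_anova(x)
    assert res.f_stat == pytest.approx(f_expect, rel=1e-12)


def test_rm_anova_matches_pingouin():
    rng = np.random.default_rng(19)
    x = rng.normal(0, 1, (10, 4)) + rng.normal(0, 2, (10, 1))
    res = rm_anova(x)
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(10), 4),
        "level": np.tile(np.arange(4), 10),
        "y": x.ravel(),
    })
    ref = pg.rm_anova(data=df, dv="y", within="level", subject="subject")
    assert res.f_stat == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
    assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)


def test_rm_anova_invariances():
    rng = np.random.default_rng(23)
    x = rng.normal(0, 1, (8, 5))
    base = rm_anova(x).f_stat
    shifted = rm_anova(x + rng.normal(0, 5, (8, 1))).f_stat
    scaled = rm_anova(3.7 * x).f_stat
    assert shifted == pytest.approx(base, rel=1e-9)
    assert scaled == pytest.approx(base, rel=1e-9)


def test_bonferroni_identical_columns():
    x = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
    out = bonferroni_pairwise(x)
    assert all(rec["p_bonferroni"] == 1.0 for rec in out)


def test_bonferroni_two_levels_no_correction():
    rng = np.random.default_rng(31)
    x = rng.normal(0, 1, (10, 2))
    rec = bonferroni_pairwise(x)[0]
    assert rec["p_bonferroni"] == pytest.approx(rec["p_raw"])


def test_bonferroni_five_levels_matches_paired_t_times_ten():
    rng = np.random.default_rng(37)
    x = rng.normal(0, 1, (12, 5))
    x[:, 3] += 2.0
    from scipy.stats import ttest_rel

    out = bonferroni_pairwise(x, levels=[4, 8, 16, 32, 64])
    for rec in out:
        i = [4, 8, 16, 32, 64].index(rec["level_i"])
        j = [4, 8, 16, 32, 64].index(rec["level_j"])
        raw = ttest_rel(x[:, i], x[:, j]).pvalue
        assert rec["p_bonferroni"] == pytest.approx(min(1.0, raw * 10))


def test_significance_stars_convention():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.005) == "**"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(5e-5) == "****"


def test_type_one_error_is_nominal():
    """Under the null the RM-ANOVA rejects at close to the 5% level."""
    rng = np.random.default_rng(99)
    rejections = 0
    n_sim = 2000
    for _ in range(n_sim):
        x = rng.normal(0, 1, (22, 5)) + rng.normal(0, 2, (22, 1))
        if rm_anova(x).p_value < 0.05:
            rejections += 1
    assert rejections / n_sim == pytest.approx(0.05, abs=0.02)
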