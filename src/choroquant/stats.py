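"""Repeatability and averaging-effect statistics.

Implements the reliability battery used for test-retest OCT studies —
within-subject SD, coefficient of repeatability (CoR = 1.96*sqrt(2)*Sw),
two-way absolute-agreement ICC, Bland-Altman limits of agreement — and the
one-way repeated-measures ANOVA (subjects as blocks) with Bonferroni
pairwise comparisons used to compare averaging levels.

All quantities are computed from explicit sums-of-squares decompositions so
they can be cross-checked against general-purpose statistical packages.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

COR_FACTOR = 1.96 * np.sqrt(2.0)

#: significance stars convention for pairwise plots
_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in _STAR_LEVELS:
        if p < thr:
            return stars
    return "ns"


@dataclass(frozen=True)
class RepeatPairs:
    """Per-subject (measurement 1, measurement 2) pairs for one parameter."""

    m1: np.ndarray
    m2: np.ndarray

    def __post_init__(self):
        a, b = np.asarray(self.m1, float), np.asarray(self.m2, float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("need two equal-length 1D measurement arrays")
        if a.size < 2:
            raise ValueError("at least two subjects required")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("measurements must be finite")

    @property
    def n(self) -> int:
        return np.asarray(self.m1).size

    @property
    def diffs(self) -> np.ndarray:
        return np.asarray(self.m1, float) - np.asarray(self.m2, float)

    @property
    def table(self) -> np.ndarray:
        return np.column_stack([self.m1, self.m2]).astype(float)


@dataclass(frozen=True)
class ReliabilityStats:
    icc: float
    sw: float
    cor: float
    ba_mean_diff: float
    ba_loa_low: float
    ba_loa_high: float
    ba_ci_low: float
    ba_ci_high: float


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    pairwise: list = field(default_factory=list)


def within_subject_sd(pairs: RepeatPairs) -> float:
    """Sw = sqrt(mean(d_i^2) / 2): the rooted within-subject mean square
    of a two-replicate one-way ANOVA."""
    d = pairs.diffs
    return float(np.sqrt(np.mean(d**2) / 2.0))


def coefficient_of_repeatability(pairs: RepeatPairs) -> float:
    """CoR = 1.96 * sqrt(2) * Sw — bounds 95% of test-retest differences."""
    return COR_FACTOR * within_subject_sd(pairs)


def icc_agreement(pairs: RepeatPairs) -> float:
    """Two-way mixed-effects, absolute-agreement, single-measurement ICC
    (McGraw-Wong A,1) from the n x 2 two-way ANOVA decomposition."""
    x = pairs.table
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("ICC undefined: zero total variance")
    ss_rows = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_tot - ss_rows - ss_cols, 0.0) / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0.0:
        return float("nan")
    return float((ms_r - ms_e) / denom)


def bland_altman(pairs: RepeatPairs) -> ReliabilityStats:
    """Full reliability summary: ICC, Sw/CoR and Bland-Altman agreement.

    LoA are mean difference ± 1.96 * SD(d) (sample SD); the 95% CI of the
    mean difference uses the t distribution with n-1 df.
    """
    d = pairs.diffs
    n = pairs.n
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    t_crit = float(sps.t.ppf(0.975, n - 1))
    sw = within_subject_sd(pairs)
    try:
        icc = icc_agreement(pairs)
    except ValueError:
        icc = float("nan")
    return ReliabilityStats(
        icc=icc,
        sw=sw,
        cor=COR_FACTOR * sw,
        ba_mean_diff=mean_d,
        ba_loa_low=mean_d - 1.96 * sd_d,
        ba_loa_high=mean_d + 1.96 * sd_d,
        ba_ci_low=mean_d - t_crit * sd_d / np.sqrt(n),
        ba_ci_high=mean_d + t_crit * sd_d / np.sqrt(n),
    )


def _check_table(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete n_subjects x k_levels table, n,k >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("table must be finite")
    return x


def rm_anova(values) -> AnovaResult:
    """One-way repeated-measures ANOVA (no sphericity correction).

    F = MS_treatment / MS_error from the subject-blocked decomposition;
    a fully degenerate table (no treatment and no error variance) yields
    F = 0, p = 1.
    """
    x = _check_table(values)
    n, k = x.shape
    grand = x.mean()
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_treat = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = max(ss_tot - ss_subj - ss_treat, 0.0)
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    ms_treat = ss_treat / df_num
    ms_err = ss_err / df_den
    if ms_err == 0.0:
        if ms_treat == 0.0:
            return AnovaResult(0.0, df_num, df_den, 1.0)
        return AnovaResult(float("inf"), df_num, df_den, 0.0)
    f = ms_treat / ms_err
    p = float(sps.f.sf(f, df_num, df_den))
    return AnovaResult(float(f), df_num, df_den, p)


def bonferroni_pairwise(values, levels=None) -> list[dict]:
    """Paired t-tests between all level pairs with Bonferroni correction.

    Returns one record per pair: level_i, level_j, mean_diff, raw and
    adjusted p, and the star annotation of the adjusted p.
    """
    x = _check_table(values)
    n, k = x.shape
    if levels is None:
        levels = list(range(k))
    if len(levels) != k:
        raise ValueError("levels must label every column")
    n_pairs = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            d = x[:, i] - x[:, j]
            if np.allclose(d, 0.0):
                p_raw = 1.0
            elif np.std(d, ddof=1) == 0.0:
                p_raw = 0.0
            else:
                p_raw = float(sps.ttest_rel(x[:, i], x[:, j]).pvalue)
            p_adj = min(1.0, p_raw * n_pairs)
            out.append(
                {
                    "level_i": levels[i],
                    "level_j": levels[j],
                    "mean_diff": float(d.mean()),
                    "p_raw": p_raw,
                    "p_bonferroni": p_adj,
                    "stars": significance_stars(p_adj),
                }
            )
    return out


def rm_anova_with_pairwise(values, levels=None) -> AnovaResult:
    res = rm_anova(values)
    return AnovaResult(res.f_stat, res.df_num, res.df_den, res.p_value,
                       bonferroni_pairwise(values, levels))
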