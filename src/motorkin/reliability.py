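"""Relative and absolute test-retest reliability statistics.

Given an n-subjects x k-trials matrix of one motor variable, this module
computes:

* a one-factor repeated-measures ANOVA (subjects, trials, residual) with
  Mauchly's sphericity test on the orthonormal-contrast covariance and the
  Greenhouse-Geisser epsilon correction of the trial F test;
* the intraclass correlation coefficient ICC(1,1) from the one-way
  (subjects) decomposition with its exact F-based confidence interval
  (Shrout-Fleiss construction), plus the two-way consistency form ICC(3,1)
  behind a flag;
* the standard error of measurement SEM = sqrt(within-subject mean square)
  and the coefficient of variation CV = 100 * SEM / grand mean, flagged
  acceptable at 10% or below;
* a standardized between-attempt effect size (trial 3 minus trial 1, in
  units of the trial-1 SD) with a bias-corrected bootstrap CI; and
* active-vs-sedentary group comparisons that pick Student's t or the
  Wilcoxon-Mann-Whitney test from normality and homoscedasticity checks.

ICC categories follow the conventional bands: below 0.50 poor, 0.50-0.69
moderate, 0.70-0.89 high, 0.90 and above excellent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "IccResult",
    "EffectSize",
    "GroupComparison",
    "ReliabilityRow",
    "oneway_mean_squares",
    "rm_anova",
    "icc_oneway",
    "icc_twoway_consistency",
    "sem_abs",
    "cv_percent",
    "categorize_icc",
    "effect_size",
    "compare_groups",
    "reliability_row",
    "CV_ACCEPTABLE_PCT",
    "ES_MODERATE",
    "ES_LARGE",
]

CV_ACCEPTABLE_PCT = 10.0
ES_MODERATE = 0.41
ES_LARGE = 0.70


def _as_matrix(X: np.ndarray, min_n: int = 2) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an n x k matrix")
    n, k = X.shape
    if n < min_n or k < 2:
        raise ValueError(f"need at least {min_n} subjects and 2 trials, "
                         f"got {n} x {k}")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains missing or non-finite cells; drop "
                         "incomplete rows first")
    return X


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """One-factor repeated-measures decomposition with sphericity handling."""

    n: int
    k: int
    ss_subjects: float
    ss_trials: float
    ss_residual: float
    ms_subjects: float
    ms_trials: float
    ms_residual: float
    f_trials: float
    df_trials: float
    df_residual: float
    p_uncorrected: float
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    df_trials_adj: float
    df_residual_adj: float
    p_adjusted: float
    sphericity_assumed: bool
    degenerate: bool = False

    @property
    def ss_total(self) -> float:
        return self.ss_subjects + self.ss_trials + self.ss_residual

    @property
    def p(self) -> float:
        """p-value after the Mauchly / Greenhouse-Geisser decision."""
        return self.p_uncorrected if self.sphericity_assumed else self.p_adjusted


def oneway_mean_squares(X: np.ndarray) -> tuple[float, float]:
    """(MS between subjects, MS within subjects) of the one-way layout."""
    X = _as_matrix(X)
    n, k = X.shape
    row_means = X.mean(axis=1)
    grand = X.mean()
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((X - row_means[:, None]) ** 2) / (n * (k - 1))
    return float(msb), float(msw)


def _mauchly(X: np.ndarray) -> tuple[float, float]:
    """Mauchly's W on the covariance of k-1 orthonormal contrasts."""
    n, k = X.shape
    # orthonormal (Helmert) contrast matrix, (k-1) x k
    C = np.zeros((k - 1, k))
    for i in range(k - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1.0)
        C[i] /= np.linalg.norm(C[i])
    S = np.cov(X, rowvar=False, ddof=1)
    A = C @ S @ C.T
    d = k - 1
    eig = np.linalg.eigvalsh(A)
    tr = float(eig.sum())
    if tr <= 0 or np.any(eig <= 0):
        return 0.0, 0.0
    W = float(np.prod(eig) / (tr / d) ** d)
    df = d * (d + 1) // 2 - 1
    if df <= 0:
        return 1.0, 1.0
    # Box's chi-square approximation with the second-order correction term
    f = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1.0))
    w2 = ((d + 2.0) * (d - 1.0) * (d - 2.0)
          * (2.0 * d**3 + 6.0 * d**2 + 3.0 * k + 2.0)
          / (288.0 * ((n - 1.0) * d * f) ** 2))
    chi2 = -f * (n - 1.0) * np.log(W)
    p1 = stats.chi2.sf(chi2, df)
    p2 = stats.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return W, p


def _gg_epsilon(X: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the trial covariance matrix."""
    n, k = X.shape
    S = np.cov(X, rowvar=False, ddof=1)
    # double-centered covariance
    row = S.mean(axis=0, keepdims=True)
    col = S.mean(axis=1, keepdims=True)
    Sc = S - row - col + S.mean()
    d = k - 1
    num = np.trace(Sc) ** 2
    den = d * np.sum(Sc * Sc)
    if den <= 0:
        return 1.0
    eps = float(num / den)
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova(X: np.ndarray, alpha: float = 0.05) -> AnovaResult:
    """One-factor (trial) repeated-measures ANOVA with sphericity logic.

    The Greenhouse-Geisser adjusted p-value is adopted iff Mauchly's test
    rejects sphericity at ``alpha``; with k = 2 sphericity holds trivially
    (epsilon = 1, Mauchly skipped).  Zero residual variance yields an
    infinite F flagged degenerate.
    """
    X = _as_matrix(X, min_n=3)
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_subj = float(k * np.sum((row_means - grand) ** 2))
    ss_trial = float(n * np.sum((col_means - grand) ** 2))
    ss_tot = float(np.sum((X - grand) ** 2))
    ss_res = max(ss_tot - ss_subj - ss_trial, 0.0)
    df_t, df_r = float(k - 1), float((n - 1) * (k - 1))
    ms_subj = ss_subj / (n - 1)
    ms_trial = ss_trial / df_t
    ms_res = ss_res / df_r
    degenerate = ms_res <= 0
    if degenerate:
        f = np.inf if ms_trial > 0 else np.nan
        p_unc = 0.0 if ms_trial > 0 else np.nan
    else:
        f = ms_trial / ms_res
        p_unc = float(stats.f.sf(f, df_t, df_r))
    if k == 2 or degenerate:
        w, w_p, eps = 1.0, 1.0, 1.0
    else:
        w, w_p = _mauchly(X)
        eps = _gg_epsilon(X)
    sphericity = bool(w_p >= alpha)
    df_t_adj, df_r_adj = eps * df_t, eps * df_r
    if degenerate:
        p_adj = p_unc
    else:
        p_adj = float(stats.f.sf(f, df_t_adj, df_r_adj))
    return AnovaResult(
        n=n, k=k,
        ss_subjects=ss_subj, ss_trials=ss_trial, ss_residual=ss_res,
        ms_subjects=float(ms_subj), ms_trials=float(ms_trial),
        ms_residual=float(ms_res),
        f_trials=float(f), df_trials=df_t, df_residual=df_r,
        p_uncorrected=p_unc,
        mauchly_w=float(w), mauchly_p=float(w_p), gg_epsilon=float(eps),
        df_trials_adj=float(df_t_adj), df_residual_adj=float(df_r_adj),
        p_adjusted=p_adj, sphericity_assumed=sphericity,
        degenerate=bool(degenerate),
    )


# --------------------------------------------------------------------------
# ICC / SEM / CV
# --------------------------------------------------------------------------


@dataclass
class IccResult:
    icc: float
    ci_lower: float
    ci_upper: float
    form: str  # "ICC(1,1)" or "ICC(3,1)"
    alpha: float


def icc_oneway(X: np.ndarray, alpha: float = 0.05) -> IccResult:
    """One-way random single-measure ICC(1,1) with its exact F-based CI.

    ICC = (MSB - MSW) / (MSB + (k-1) MSW) from the one-way (subjects)
    decomposition; the confidence bounds invert the F statistic MSB/MSW
    (Shrout-Fleiss construction).  A constant matrix has no defined ICC
    and returns NaN with a warning.
    """
    X = _as_matrix(X)
    n, k = X.shape
    msb, msw = oneway_mean_squares(X)
    if msb == 0 and msw == 0:
        warnings.warn("constant matrix: between- and within-subject mean "
                      "squares are both zero, ICC undefined", stacklevel=2)
        return IccResult(np.nan, np.nan, np.nan, "ICC(1,1)", alpha)
    if msw == 0:
        return IccResult(1.0, 1.0, 1.0, "ICC(1,1)", alpha)
    fobs = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    fl = fobs / stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
    fu = fobs * stats.f.ppf(1.0 - alpha / 2.0, df2, df1)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    lo = (fl - 1.0) / (fl + (k - 1.0))
    hi = (fu - 1.0) / (fu + (k - 1.0))
    return IccResult(float(icc), float(lo), float(hi), "ICC(1,1)", alpha)


def icc_twoway_consistency(X: np.ndarray, alpha: float = 0.05) -> IccResult:
    """Two-way mixed consistency ICC(3,1), from the two-way decomposition."""
    X = _as_matrix(X, min_n=3)
    res = rm_anova(X)
    msb, mse = res.ms_subjects, res.ms_residual
    if msb == 0 and mse == 0:
        warnings.warn("constant matrix: ICC undefined", stacklevel=2)
        return IccResult(np.nan, np.nan, np.nan, "ICC(3,1)", alpha)
    if mse == 0:
        return IccResult(1.0, 1.0, 1.0, "ICC(3,1)", alpha)
    n, k = res.n, res.k
    fobs = msb / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = fobs / stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
    fu = fobs * stats.f.ppf(1.0 - alpha / 2.0, df2, df1)
    icc = (msb - mse) / (msb + (k - 1) * mse)
    lo = (fl - 1.0) / (fl + (k - 1.0))
    hi = (fu - 1.0) / (fu + (k - 1.0))
    return IccResult(float(icc), float(lo), float(hi), "ICC(3,1)", alpha)


def sem_abs(X: np.ndarray) -> float:
    """Standard error of measurement: sqrt of the within-subject mean square."""
    _, msw = oneway_mean_squares(X)
    return float(np.sqrt(msw))


def cv_percent(X: np.ndarray) -> float:
    """Coefficient of variation: 100 * SEM / grand mean of all cells."""
    X = _as_matrix(X)
    grand = float(X.mean())
    if grand <= 0:
        warnings.warn("grand mean <= 0: CV ratio has undefined semantics; "
                      "reporting the signed ratio", stacklevel=2)
    return float(100.0 * sem_abs(X) / grand)


def cv_acceptable(cv: float, threshold: float = CV_ACCEPTABLE_PCT) -> bool:
    """Conventional acceptability: CV of 10% or less."""
    return bool(cv <= threshold)


def categorize_icc(icc: float) -> str:
    """Conventional ICC bands: <0.50 poor, 0.50-0.69 moderate, 0.70-0.89
    high, >=0.90 excellent; NaN maps to "undefined"."""
    if not np.isfinite(icc):
        return "undefined"
    if icc >= 0.90:
        return "excellent"
    if icc >= 0.70:
        return "high"
    if icc >= 0.50:
        return "moderate"
    return "poor"


# --------------------------------------------------------------------------
# effect size and group comparison
# --------------------------------------------------------------------------


@dataclass
class EffectSize:
    es: float
    ci_lower: float
    ci_upper: float
    band: str  # small / moderate / large


def es_band(es: float) -> str:
    a = abs(es)
    if not np.isfinite(a):
        return "undefined"
    if a >= ES_LARGE:
        return "large"
    if a >= ES_MODERATE:
        return "moderate"
    return "small"


def effect_size(X: np.ndarray, n_boot: int = 2000, seed: int = 0,
                ci_level: float = 0.90) -> EffectSize:
    """Standardized change across attempts: (mean trial k - mean trial 1)
    divided by the trial-1 SD, with a bias-corrected bootstrap CI
    (resampling subjects)."""
    X = _as_matrix(X)
    sd1 = float(np.std(X[:, 0], ddof=1))
    if sd1 == 0:
        warnings.warn("trial-1 SD is zero: effect size undefined",
                      stacklevel=2)
        return EffectSize(np.nan, np.nan, np.nan, "undefined")

    def es_of(M: np.ndarray) -> float:
        s = np.std(M[:, 0], ddof=1)
        if s == 0:
            return np.nan
        return float((M[:, -1].mean() - M[:, 0].mean()) / s)

    es_hat = es_of(X)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    boots = np.array([
        es_of(X[rng.integers(0, n, size=n)]) for _ in range(n_boot)
    ])
    boots = boots[np.isfinite(boots)]
    if boots.size < 10:
        return EffectSize(es_hat, np.nan, np.nan, es_band(es_hat))
    # bias-corrected percentile bootstrap
    prop = np.clip(np.mean(boots < es_hat), 1e-6, 1 - 1e-6)
    z0 = stats.norm.ppf(prop)
    a = (1.0 - ci_level) / 2.0
    lo_q = stats.norm.cdf(2 * z0 + stats.norm.ppf(a))
    hi_q = stats.norm.cdf(2 * z0 + stats.norm.ppf(1 - a))
    lo, hi = np.quantile(boots, [lo_q, hi_q])
    return EffectSize(es_hat, float(lo), float(hi), es_band(es_hat))


@dataclass
class GroupComparison:
    test: str  # "student-t" or "wilcoxon-mann-whitney"
    statistic: float
    p: float
    estimate: float  # mean (t) or Hodges-Lehmann median (MWU) difference
    ci_lower: float
    ci_upper: float
    n_a: int
    n_b: int


def compare_groups(values: np.ndarray, labels: np.ndarray,
                   alpha: float = 0.05,
                   group_names: tuple[str, str] = ("active", "sedentary"),
                   ) -> GroupComparison:
    """Two-group comparison choosing Student's t or the rank test.

    Shapiro-Wilk per group and Levene across groups at ``alpha`` select
    Student's t (all pass) else the Wilcoxon-Mann-Whitney test.  ``values``
    are the per-subject means of the attempts; ``labels`` their group names.
    Groups below n = 3 make normality untestable: the rank test is used with
    a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    a = values[labels == group_names[0]]
    b = values[labels == group_names[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    use_rank = False
    if min(a.size, b.size) < 3:
        warnings.warn("a group has fewer than 3 subjects: normality is "
                      "untestable, using the rank test", stacklevel=2)
        use_rank = True
    else:
        norm_ok = (stats.shapiro(a).pvalue >= alpha
                   and stats.shapiro(b).pvalue >= alpha)
        var_ok = stats.levene(a, b).pvalue >= alpha
        use_rank = not (norm_ok and var_ok)
    if not use_rank:
        res = stats.ttest_ind(a, b)
        ci = res.confidence_interval(1.0 - alpha)
        return GroupComparison(
            test="student-t", statistic=float(res.statistic),
            p=float(res.pvalue), estimate=float(a.mean() - b.mean()),
            ci_lower=float(ci.low), ci_upper=float(ci.high),
            n_a=a.size, n_b=b.size,
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    hl = float(np.median(diffs))
    # distribution-free CI on the location shift (normal approximation)
    na, nb = a.size, b.size
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(na * nb * (na + nb + 1) / 12.0)
    kk = int(np.floor(na * nb / 2.0 - z * se))
    kk = max(kk, 0)
    lo = diffs[kk] if kk < diffs.size else diffs[0]
    hi = diffs[-1 - kk] if kk < diffs.size else diffs[-1]
    return GroupComparison(
        test="wilcoxon-mann-whitney", statistic=float(res.statistic),
        p=float(res.pvalue), estimate=hl,
        ci_lower=float(lo), ci_upper=float(hi), n_a=na, n_b=nb,
    )


# --------------------------------------------------------------------------
# per-variable reliability row
# --------------------------------------------------------------------------


@dataclass
class ReliabilityRow:
    """Full reliability summary for one motor variable."""

    variable: str
    n: int
    k: int
    icc: float
    ci_lower: float
    ci_upper: float
    category: str
    sem: float
    cv: float
    cv_acceptable: bool
    anova: AnovaResult
    es: EffectSize
    n_dropped: int = 0


def reliability_row(variable: str, X: np.ndarray, alpha: float = 0.05,
                    icc_form: str = "oneway", es_seed: int = 0,
                    cv_threshold: float = CV_ACCEPTABLE_PCT,
                    n_dropped: int = 0) -> ReliabilityRow:
    """Assemble ICC / SEM / CV / ANOVA / ES for one variable's n x k matrix."""
    if icc_form == "oneway":
        icc = icc_oneway(X, alpha)
    elif icc_form == "twoway":
        icc = icc_twoway_consistency(X, alpha)
    else:
        raise ValueError(f"unknown icc_form '{icc_form}'")
    sem = sem_abs(X)
    cv = cv_percent(X)
    return ReliabilityRow(
        variable=variable, n=X.shape[0], k=X.shape[1],
        icc=icc.icc, ci_lower=icc.ci_lower, ci_upper=icc.ci_upper,
        category=categorize_icc(icc.icc),
        sem=sem, cv=cv, cv_acceptable=cv_acceptable(cv, cv_threshold),
        anova=rm_anova(X, alpha),
        es=effect_size(X, seed=es_seed),
        n_dropped=n_dropped,
    )
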