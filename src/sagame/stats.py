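"""Inferential toolkit for the game analyses.

Covers the analyses the pipeline reports: Welch's unequal-variances t-test
with Cohen's d, a two-way mixed (split-plot) ANOVA — one between-subject
group factor, one within-subject phase factor — with partial η² and the
Greenhouse–Geisser sphericity correction, polynomial (linear) contrasts over
the three phases, ordinary least-squares regression with adjusted R², nested
model comparison by the ΔR² F-test, and the Pearson correlation.

Significance is evaluated two-sided at α = 0.05 with no multiple-testing
correction, matching the reporting style of the analyses this package
reproduces.  The split-plot ANOVA is computed from sums of squares in closed
form; the Greenhouse–Geisser ε comes from the eigenvalues of the
double-centered pooled within-group covariance of the phase measures,
ε = (Σλ)² / ((k−1) Σλ²), bounded in [1/(k−1), 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float  # Welch-Satterthwaite, real-valued
    p: float
    cohen_d: float
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class EffectResult:
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    p_gg: float | None = None  # Greenhouse-Geisser corrected (within effects)
    df1_gg: float | None = None
    df2_gg: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    effects: Mapping[str, EffectResult]  # group, phase, interaction
    gg_epsilon: float
    n_subjects: int
    k_within: int


@dataclass(frozen=True)
class RegressionResult:
    names: tuple[str, ...]
    coef: tuple[float, ...]
    se: tuple[float, ...]
    t: tuple[float, ...]
    p: tuple[float, ...]
    r_sq: float
    adj_r_sq: float
    n: int
    n_predictors: int
    f: float
    f_p: float


@dataclass(frozen=True)
class ModelComparison:
    delta_r_sq: float
    F: float
    df1: float
    df2: float
    p: float


@dataclass(frozen=True)
class ContrastResult:
    weights: tuple[float, ...]
    mean_L: float
    t: float
    df: float
    p: float
    degenerate: bool  # zero variance in the contrast scores


def welch_t(a: Sequence[float], b: Sequence[float],
            pooled_d: bool = True) -> TTestResult:
    """Welch's unequal-variances t-test with Cohen's d.

    ``pooled_d=True`` standardizes the mean difference by the pooled sd;
    otherwise by the root mean of the two variances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        t = 0.0
        df = float(na + nb - 2)
    else:
        t = float((a.mean() - b.mean()) / np.sqrt(se2))
        df = float(se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
    p = float(2 * sps.t.sf(abs(t), df))
    if pooled_d:
        sd = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    else:
        sd = np.sqrt((va + vb) / 2)
    d = float((a.mean() - b.mean()) / sd) if sd > 0 else 0.0
    return TTestResult(t=t, df=df, p=p, cohen_d=d,
                       mean_a=float(a.mean()), mean_b=float(b.mean()))


def gg_epsilon(wide: np.ndarray, groups: np.ndarray | None = None) -> float:
    """Greenhouse-Geisser ε from a subjects × levels matrix.

    The covariance of the within-subject measures is pooled within groups
    (group means removed), double-centered, and ε computed from its
    eigenvalues.  For k = 2 levels ε is identically 1.
    """
    wide = np.asarray(wide, dtype=float)
    n, k = wide.shape
    if k < 2:
        raise ValueError("need at least two within-subject levels")
    if k == 2:
        return 1.0
    resid = wide.copy()
    if groups is not None:
        for g in np.unique(groups):
            m = groups == g
            resid[m] -= resid[m].mean(axis=0)
    else:
        resid -= resid.mean(axis=0)
    S = resid.T @ resid / (n - (1 if groups is None else len(np.unique(groups))))
    C = np.eye(k) - np.ones((k, k)) / k
    lam = np.linalg.eigvalsh(C @ S @ C)
    lam = lam[lam > 1e-12]
    if len(lam) == 0:
        return 1.0
    eps = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def mixed_anova(data: pd.DataFrame, dv: str = "value", within: str = "phase",
                subject: str = "participant_id",
                between: str = "group") -> AnovaResult:
    """Two-way mixed ANOVA: one between-group factor, one within factor.

    Requires a balanced within design (every subject measured at every
    level) with no missing cells; raises otherwise rather than imputing.
    """
    df = data[[subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise ValueError("missing cells are not allowed")
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("missing cells are not allowed")
    k = wide.shape[1]
    groups = wide.index.get_level_values(1).to_numpy()
    levels = np.unique(groups)
    n = len(wide)
    if any((groups == g).sum() < 2 for g in levels):
        raise ValueError("need at least two subjects per group")
    Y = wide.to_numpy(dtype=float)

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    phase_means = Y.mean(axis=0)
    g_means = {g: Y[groups == g].mean() for g in levels}
    n_g = {g: (groups == g).sum() for g in levels}

    ss_total = ((Y - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * sum(n_g[g] * (g_means[g] - grand) ** 2 for g in levels)
    ss_err_between = ss_between_subj - ss_group
    ss_within = ss_total - ss_between_subj
    ss_phase = n * ((phase_means - grand) ** 2).sum()
    ss_inter = 0.0
    for g in levels:
        cell = Y[groups == g].mean(axis=0)
        ss_inter += n_g[g] * ((cell - g_means[g] - phase_means + grand) ** 2).sum()
    ss_err_within = ss_within - ss_phase - ss_inter

    g_df = len(levels) - 1
    eb_df = n - len(levels)
    ph_df = k - 1
    int_df = g_df * ph_df
    ew_df = eb_df * ph_df

    eps = gg_epsilon(Y, groups)

    def effect(ss_eff, df_eff, ss_err, df_err, within_effect):
        if df_eff == 0:
            return None
        ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, df_eff, df_err))
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        p_gg = df1_gg = df2_gg = None
        if within_effect:
            df1_gg, df2_gg = eps * df_eff, eps * df_err
            p_gg = float(sps.f.sf(F, df1_gg, df2_gg))
        return EffectResult(F=float(F), df1=float(df_eff), df2=float(df_err),
                            p=p, partial_eta_sq=float(eta), p_gg=p_gg,
                            df1_gg=df1_gg, df2_gg=df2_gg)

    effects = {"phase": effect(ss_phase, ph_df, ss_err_within, ew_df, True)}
    if g_df > 0:
        effects["group"] = effect(ss_group, g_df, ss_err_between, eb_df, False)
        effects["interaction"] = effect(ss_inter, int_df, ss_err_within, ew_df, True)
    return AnovaResult(effects=effects, gg_epsilon=eps, n_subjects=n, k_within=k)


def linear_contrast(values: np.ndarray | pd.DataFrame,
                    weights: Sequence[float] = (-1.0, 0.0, 1.0)) -> ContrastResult:
    """Polynomial (default linear) contrast over within-subject levels.

    ``values`` is a subjects × levels matrix; per subject the contrast score
    L = Σ w_j x_j is formed and tested against zero with a one-sample t.
    Zero-variance contrast scores are flagged as degenerate.
    """
    Y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if Y.shape[1] != len(w):
        raise ValueError("weights must match the number of levels")
    L = Y @ w
    n = len(L)
    mean_L = float(L.mean())
    sd = L.std(ddof=1) if n > 1 else 0.0
    if sd == 0:
        return ContrastResult(tuple(w), mean_L, t=0.0, df=float(n - 1),
                              p=1.0 if mean_L == 0 else 0.0, degenerate=True)
    t = mean_L / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return ContrastResult(tuple(w), mean_L, t=float(t), df=float(n - 1), p=p,
                          degenerate=False)


def ols_regression(y: Sequence[float], X: np.ndarray,
                   names: Sequence[str] | None = None) -> RegressionResult:
    """OLS with intercept; coefficients, adjusted R² and the overall F."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > n_predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, Xc).fit()
    names = tuple(["intercept"] + (list(names) if names
                                   else [f"x{i + 1}" for i in range(p)]))
    return RegressionResult(
        names=names, coef=tuple(fit.params), se=tuple(fit.bse),
        t=tuple(fit.tvalues), p=tuple(fit.pvalues), r_sq=float(fit.rsquared),
        adj_r_sq=float(fit.rsquared_adj), n=n, n_predictors=p,
        f=float(fit.fvalue), f_p=float(fit.f_pvalue))


def nested_f(reduced: RegressionResult, full: RegressionResult) -> ModelComparison:
    """ΔR² F-test for nested OLS models fit to the same response."""
    if full.n != reduced.n:
        raise ValueError("models must be fit to the same response vector")
    dp = full.n_predictors - reduced.n_predictors
    if dp == 0 and reduced.names == full.names:
        df2 = full.n - full.n_predictors - 1
        return ModelComparison(delta_r_sq=0.0, F=0.0, df1=0.0,
                               df2=float(df2), p=1.0)
    if dp <= 0 or not set(reduced.names) <= set(full.names):
        raise ValueError("models are not nested (reduced ⊄ full)")
    delta = full.r_sq - reduced.r_sq
    df2 = full.n - full.n_predictors - 1
    F = (delta / dp) / ((1 - full.r_sq) / df2) if full.r_sq < 1 else np.inf
    p = float(sps.f.sf(F, dp, df2))
    return ModelComparison(delta_r_sq=float(delta), F=float(F), df1=float(dp),
                           df2=float(df2), p=p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y)[0])
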