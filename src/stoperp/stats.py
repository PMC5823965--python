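"""Statistical procedures for within-subject ERP/behavioral designs.

Paired t tests with two Cohen's d variants, 2x2 fully repeated-measures
ANOVA with partial eta squared, standardized multiple regression,
Pearson correlation, Steiger's Z for dependent correlations sharing one
variable (classic and the pooled-correlation "updated" variant), paired
t power from the noncentral t distribution, Kolmogorov-Smirnov normality
screening (Lilliefors by default), and Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

from .errors import AnalysisError, ContractError


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d_av: float  # |mean diff| / mean of the two condition SDs
    d_z: float  # |t| / sqrt(n)
    mean_diff: float


def cohens_d_av(mean_diff: float, sd_x: float, sd_y: float) -> float:
    """|mean difference| divided by the average of the two condition SDs."""
    denom = 0.5 * (sd_x + sd_y)
    if denom == 0:
        return 0.0
    return abs(mean_diff) / denom


def paired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-tailed paired t test with d_av and d_z effect sizes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ContractError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ContractError("paired t needs n >= 2")
    diff = x - y
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if sd_diff == 0:
        t = 0.0 if mean_diff == 0 else math.inf * np.sign(mean_diff)
        p = 1.0 if mean_diff == 0 else 0.0
    else:
        t = mean_diff / (sd_diff / math.sqrt(n))
        p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TTestResult(
        t=float(t),
        df=n - 1,
        p=float(p),
        d_av=cohens_d_av(mean_diff, float(x.std(ddof=1)), float(y.std(ddof=1))),
        d_z=0.0 if not math.isfinite(t) else abs(t) / math.sqrt(n),
        mean_diff=mean_diff,
    )


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    factor_a: AnovaEffect
    factor_b: AnovaEffect
    interaction: AnovaEffect

    def as_dict(self) -> dict:
        return {"A": self.factor_a, "B": self.factor_b, "AxB": self.interaction}


def partial_eta_sq(F: float, df_effect: int, df_error: int) -> float:
    """Partial eta squared from an F ratio: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ContractError("F must be non-negative")
    if df_effect < 1 or df_error < 1:
        raise ContractError("degrees of freedom must be >= 1")
    return F * df_effect / (F * df_effect + df_error)


def rm_anova_2x2(values: np.ndarray) -> AnovaResult:
    """Two-way fully repeated-measures ANOVA on a subjects x 2 x 2 table.

    Within-subject sums-of-squares decomposition with one observation
    per cell; every effect is tested against its own effect-by-subject
    interaction with df = (1, n-1).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[1:] != (2, 2):
        raise ContractError("expected a subjects x 2 x 2 array")
    if not np.all(np.isfinite(values)):
        raise AnalysisError("missing cells in the repeated-measures table")
    n = values.shape[0]
    if n < 2:
        raise ContractError("rm ANOVA needs >= 2 subjects")

    grand = values.mean()
    subj = values.mean(axis=(1, 2))  # per-subject means
    a_means = values.mean(axis=(0, 2))  # factor A marginal means
    b_means = values.mean(axis=(0, 1))
    ab_means = values.mean(axis=0)

    ss_a = 2 * n * np.sum((a_means - grand) ** 2)
    ss_b = 2 * n * np.sum((b_means - grand) ** 2)
    ss_ab = n * np.sum(
        (ab_means - a_means[:, None] - b_means[None, :] + grand) ** 2
    )
    subj_a = values.mean(axis=2)  # subjects x A
    subj_b = values.mean(axis=1)
    ss_as = 2 * np.sum((subj_a - a_means[None, :] - subj[:, None] + grand) ** 2)
    ss_bs = 2 * np.sum((subj_b - b_means[None, :] - subj[:, None] + grand) ** 2)
    resid = (
        values
        - ab_means[None, :, :]
        - subj_a[:, :, None]
        - subj_b[:, None, :]
        + a_means[None, :, None]
        + b_means[None, None, :]
        + subj[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2)

    df_err = n - 1
    effects = []
    for ss_eff, ss_err in ((ss_a, ss_as), (ss_b, ss_bs), (ss_ab, ss_abs)):
        ms_eff = ss_eff / 1
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else math.inf)
        p = float(sps.f.sf(F, 1, df_err)) if math.isfinite(F) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        effects.append(AnovaEffect(float(F), 1, df_err, p, float(eta)))
    return AnovaResult(*effects)


@dataclass(frozen=True)
class RegressionResult:
    r_squared: float
    adj_r_squared: float
    F: float
    df_model: int
    df_resid: int
    p_model: float
    betas: np.ndarray  # standardized coefficients
    t_values: np.ndarray
    p_values: np.ndarray
    predictor_names: tuple


def ols_regression_standardized(
    y: Sequence[float],
    predictors: dict,
) -> RegressionResult:
    """OLS on z-scored outcome and predictors (standardized betas).

    ``predictors`` maps name -> values.  Raises on rank deficiency,
    naming the offending predictor.
    """
    names = tuple(predictors.keys())
    X = np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if y.size != n:
        raise ContractError("outcome and predictors must have equal length")
    if n <= k + 1:
        raise ContractError("need n > k + 1 observations")
    sds = X.std(axis=0, ddof=1)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise AnalysisError(f"predictor {names[j]!r} has zero variance")
    if y.std(ddof=1) == 0:
        raise AnalysisError("outcome has zero variance")
    Z = (X - X.mean(axis=0)) / sds
    zy = (y - y.mean()) / y.std(ddof=1)
    if np.linalg.matrix_rank(Z) < k:
        corr = np.corrcoef(Z, rowvar=False)
        off = np.abs(corr - np.eye(k))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise AnalysisError(
            f"collinear predictors: {names[i]!r} and {names[j]!r}"
        )
    model = sm.OLS(zy, sm.add_constant(Z)).fit()
    return RegressionResult(
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
        F=float(model.fvalue),
        df_model=k,
        df_resid=n - k - 1,
        p_model=float(model.f_pvalue),
        betas=np.asarray(model.params[1:]),
        t_values=np.asarray(model.tvalues[1:]),
        p_values=np.asarray(model.pvalues[1:]),
        predictor_names=names,
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-tailed t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ContractError("samples must have equal length")
    if x.size < 3:
        raise ContractError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise AnalysisError("zero-variance input to correlation")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=x.size, p=float(res.pvalue))


@dataclass(frozen=True)
class SteigerResult:
    Z: float
    p: float
    variant: str


def steiger_z(
    r12: float, r13: float, r23: float, n: int, variant: str = "updated"
) -> SteigerResult:
    """Compare two dependent correlations sharing variable 1.

    Fisher-z transforms r12 and r13 and uses the asymptotic covariance
    of dependent correlations.  ``variant='updated'`` plugs the average
    of the two compared correlations into the covariance (the pooled
    form recommended as a refinement of the classic statistic);
    ``variant='classic'`` uses the individual correlations.  The sign of
    Z follows r12 - r13; p is two-tailed.
    """
    for r in (r12, r13, r23):
        if not (-1.0 <= r <= 1.0):
            raise ContractError("correlations must lie in [-1, 1]")
    if abs(r12) == 1.0 or abs(r13) == 1.0:
        raise ContractError("degenerate |r| = 1 input")
    if n < 4:
        raise ContractError("Steiger's Z needs n >= 4")
    z12 = math.atanh(r12)
    z13 = math.atanh(r13)
    if variant == "updated":
        rbar = 0.5 * (r12 + r13)
        psi = r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)
        cov = psi / (1 - rbar**2) ** 2
    elif variant == "classic":
        psi = r23 * (1 - r12**2 - r13**2) - 0.5 * r12 * r13 * (
            1 - r12**2 - r13**2 - r23**2
        )
        cov = psi / ((1 - r12**2) * (1 - r13**2))
    else:
        raise ContractError("variant must be 'updated' or 'classic'")
    Z = (z12 - z13) * math.sqrt((n - 3) / max(2.0 - 2.0 * cov, 1e-12))
    p = 2.0 * sps.norm.sf(abs(Z))
    return SteigerResult(Z=float(Z), p=float(p), variant=variant)


def power_paired_t(
    n: int, dz: float, alpha: float = 0.05, tails: int = 2
) -> float:
    """Power of a paired t test from the noncentral t distribution.

    ``dz`` is the standardized mean difference (mean / SD of the paired
    differences); the noncentrality parameter is dz * sqrt(n) with
    df = n - 1.
    """
    if n < 2:
        raise ContractError("power needs n >= 2")
    if dz < 0:
        raise ContractError("dz must be >= 0")
    if not (0.0 < alpha < 1.0):
        raise ContractError("alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise ContractError("tails must be 1 or 2")
    df = n - 1
    ncp = dz * math.sqrt(n)
    if tails == 1:
        tcrit = sps.t.ppf(1 - alpha, df)
        return float(sps.nct.sf(tcrit, df, ncp))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def ks_normality(x: Sequence[float], estimated: bool = True) -> tuple:
    """Kolmogorov-Smirnov screen against a normal reference.

    With ``estimated=True`` (default) the reference mean/SD are taken
    from the sample and the p value uses the Lilliefors correction
    (table/Monte-Carlo based).  ``estimated=False`` gives the classic
    known-parameter KS p value, which is anticonservative when the
    parameters were in fact estimated.
    Returns (D, p).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ContractError("KS normality screen needs n >= 5")
    if x.std(ddof=1) == 0:
        raise AnalysisError("zero-variance input")
    if estimated:
        D, p = lilliefors(x, dist="norm")
        return float(D), float(p)
    res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m); m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ContractError("m must be >= 1")
    return np.minimum(1.0, p * m)
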