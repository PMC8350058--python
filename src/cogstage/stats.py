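"""Statistical machinery: effect sizes, exact intervals, FDR, power,
change-score ANCOVA, logistic progression models, and group comparisons.

Ordinary fits delegate to scipy/statsmodels; the rank effect size and the
two-proportion power formula are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectSizeResult",
    "BinomialCI",
    "PowerSpec",
    "cliffs_delta",
    "cramers_v",
    "exact_binomial_ci",
    "wald_binomial_ci",
    "bh_fdr",
    "two_proportion_power",
    "change_ancova",
    "logistic_progression",
    "group_compare",
    "SeparationError",
]

#: Cliff's delta magnitude bands (|d| thresholds for small/medium/large)
CLIFF_BANDS = (0.147, 0.33, 0.474)


class SeparationError(RuntimeError):
    """Logistic fit failed to converge (e.g. complete separation)."""


@dataclass(frozen=True)
class EffectSizeResult:
    kind: str  # "cliffs_delta" | "cramers_v"
    estimate: float
    magnitude_label: str


def _cliff_magnitude(d: float) -> str:
    a = abs(d)
    if a < CLIFF_BANDS[0]:
        return "negligible"
    if a < CLIFF_BANDS[1]:
        return "small"
    if a < CLIFF_BANDS[2]:
        return "medium"
    return "large"


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> EffectSizeResult:
    """Cliff's delta: P(X > Y) - P(X < Y) over all cross-group pairs.

    A rank-based effect size robust to outliers and unequal variances; ties
    contribute zero.  Computed in O((m+n) log(m+n)) from the joint ranking
    rather than by pair enumeration.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires non-empty samples")
    ys = np.sort(y)
    # for each xi: #(y < xi) - #(y > xi)
    lt = np.searchsorted(ys, x, side="left")
    gt = y.size - np.searchsorted(ys, x, side="right")
    d = float((lt - gt).sum()) / (x.size * y.size)
    return EffectSizeResult("cliffs_delta", d, _cliff_magnitude(d))


def cramers_v(table: np.ndarray | Sequence[Sequence[float]]) -> EffectSizeResult:
    """Cramer's V = sqrt(chi2 / (N * min(r-1, c-1))) for an r x c table."""
    T = np.asarray(table, float)
    if T.ndim != 2 or min(T.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (T < 0).any():
        raise ValueError("counts must be non-negative")
    if (T.sum(axis=0) == 0).any() or (T.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row/column")
    chi2 = sps.chi2_contingency(T, correction=False).statistic
    n = T.sum()
    v = float(np.sqrt(chi2 / (n * (min(T.shape) - 1))))
    # conventional V bands (half Cohen's w scaling)
    label = (
        "negligible" if v < 0.1 else "small" if v < 0.3 else "medium" if v < 0.5 else "large"
    )
    return EffectSizeResult("cramers_v", v, label)


@dataclass(frozen=True)
class BinomialCI:
    successes: int
    trials: int
    level: float
    lower: float
    upper: float
    method: str


def exact_binomial_ci(successes: int, trials: int, level: float = 0.95) -> BinomialCI:
    """Clopper-Pearson exact interval from beta quantiles."""
    k, n = int(successes), int(trials)
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= successes <= trials, trials > 0")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return BinomialCI(k, n, level, lower, upper, "clopper_pearson")


def wald_binomial_ci(successes: int, trials: int, level: float = 0.95) -> BinomialCI:
    """Normal-approximation interval, for large-denominator proportions."""
    k, n = int(successes), int(trials)
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= successes <= trials, trials > 0")
    p = k / n
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return BinomialCI(k, n, level, max(p - half, 0.0), min(p + half, 1.0), "wald")


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass(frozen=True)
class PowerSpec:
    p1: float
    p2: float
    n1: int
    n2: int
    alpha: float = 0.05


def two_proportion_power(spec: PowerSpec) -> float:
    """Power of the two-sided two-proportion z-test.

    Normal approximation without continuity correction: the null standard
    error pools the proportions (weighted by group size); the alternative
    standard error does not.
    """
    p1, p2, n1, n2 = spec.p1, spec.p2, spec.n1, spec.n2
    if not (0 < p1 < 1 and 0 < p2 < 1) or n1 <= 0 or n2 <= 0:
        raise ValueError("proportions must be in (0,1) and group sizes positive")
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z = sps.norm.ppf(1 - spec.alpha / 2)
    d = p1 - p2
    return float(
        sps.norm.cdf((d - z * se0) / se1) + sps.norm.cdf((-d - z * se0) / se1)
    )


def change_ancova(
    change: Sequence[float],
    group: Sequence[str],
    baseline: Sequence[float],
    interval: Sequence[float],
) -> dict:
    """Covariance-adjusted comparison of longitudinal change across groups.

    Fits change ~ group + baseline + interval by OLS (baseline adjusts for
    regression to the mean; interval for unequal follow-up), and returns
    covariate-adjusted group means evaluated at the covariate means, pairwise
    contrast p-values, and a nonparametric companion: a Kruskal-Wallis test
    on the residuals of the covariates-only fit.
    """
    df = pd.DataFrame(
        dict(change=np.asarray(change, float), group=list(group),
             baseline=np.asarray(baseline, float), interval=np.asarray(interval, float))
    )
    if not np.isfinite(df[["change", "baseline", "interval"]].to_numpy()).all():
        raise ValueError("covariates and change must be finite")
    levels = sorted(df["group"].unique())
    if len(levels) < 2 or df.groupby("group").size().min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    G = pd.get_dummies(df["group"], dtype=float)[levels]
    X = np.column_stack([G.to_numpy(), df[["baseline", "interval"]].to_numpy()])
    # cell-means coding: one indicator per group + covariates, no intercept
    fit = sm.OLS(df["change"].to_numpy(), X).fit()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design")
    cov_means = df[["baseline", "interval"]].mean().to_numpy()
    k = len(levels)
    adjusted = {
        lev: float(fit.params[i] + fit.params[k] * cov_means[0] + fit.params[k + 1] * cov_means[1])
        for i, lev in enumerate(levels)
    }
    contrasts = {}
    for i in range(k):
        for j in range(i + 1, k):
            L = np.zeros(X.shape[1])
            L[i], L[j] = 1.0, -1.0
            t = fit.t_test(L)
            contrasts[(levels[i], levels[j])] = dict(
                estimate=float(np.asarray(t.effect).reshape(-1)[0]),
                se=float(np.asarray(t.sd).reshape(-1)[0]),
                p=float(np.asarray(t.pvalue).reshape(-1)[0]),
            )
    # omnibus group test vs covariates-only model
    Xr = sm.add_constant(df[["baseline", "interval"]].to_numpy())
    fit_r = sm.OLS(df["change"].to_numpy(), Xr).fit()
    f_res = fit.compare_f_test(fit_r)
    resid = fit_r.resid
    groups_resid = [resid[df["group"] == lev] for lev in levels]
    kw = sps.kruskal(*groups_resid)
    return dict(
        adjusted_means=adjusted,
        contrasts=contrasts,
        omnibus_p=float(f_res[1]),
        kruskal_p=float(kw.pvalue),
        model=fit,
        group_levels=levels,
    )


def logistic_progression(
    outcome: Sequence[int],
    covariates: pd.DataFrame | dict,
    level: float = 0.95,
) -> pd.DataFrame:
    """Adjusted logistic model of progression risk.

    ``covariates`` columns typically: baseline CU_D indicator, baseline age,
    sex, literacy, follow-up years.  Returns one row per covariate with the
    odds ratio, Wald CI, and p-value.  Non-convergence or separation raises
    :class:`SeparationError` rather than returning silent estimates.
    """
    X = pd.DataFrame(covariates).astype(float)
    y = np.asarray(outcome, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    Xc = sm.add_constant(X)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
    except Exception as exc:  # PerfectSeparationError et al.
        raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge")
    if not np.isfinite(fit.bse).all() or (np.abs(fit.params) > 30).any():
        raise SeparationError("separation suspected: unbounded coefficients")
    z = sps.norm.ppf(0.5 + level / 2)
    rows = []
    for name in Xc.columns:
        if name == "const":
            continue
        b, se = fit.params[name], fit.bse[name]
        rows.append(
            dict(
                term=name,
                odds_ratio=float(np.exp(b)),
                ci_lower=float(np.exp(b - z * se)),
                ci_upper=float(np.exp(b + z * se)),
                p=float(fit.pvalues[name]),
            )
        )
    return pd.DataFrame(rows)


def _fisher_exact_rxc(T: np.ndarray) -> float:
    """Two-sided exact test of independence for an r x c count table.

    2x2 tables use the hypergeometric test directly; tables with two rows (or
    two columns) use Freeman-Halton enumeration of all tables with the
    observed margins, summing probabilities <= that of the observed table.
    Larger tables fall back to the Pearson chi-square approximation.
    """
    T = np.asarray(T, float)
    if T.shape == (2, 2):
        return float(sps.fisher_exact(T)[1])
    if T.shape[0] != 2 and T.shape[1] == 2:
        T = T.T
    if T.shape[0] != 2:
        return float(sps.chi2_contingency(T, correction=False).pvalue)
    col = T.sum(axis=0).astype(int)
    r1 = int(T[0].sum())
    n = int(T.sum())
    if n > 100_000:
        return float(sps.chi2_contingency(T, correction=False).pvalue)
    from math import lgamma

    def lchoose(a, b):
        return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)

    base = -lchoose(n, r1)
    obs_logp = base + sum(lchoose(col[j], int(T[0, j])) for j in range(len(col)))
    total = 0.0
    c = len(col)

    def rec(j: int, rem: int, acc: float) -> None:
        nonlocal total
        if j == c - 1:
            if 0 <= rem <= col[j]:
                lp = acc + lchoose(col[j], rem)
                if lp <= obs_logp + 1e-9:
                    total += np.exp(lp)
            return
        lo = max(0, rem - int(col[j + 1:].sum()))
        hi = min(col[j], rem)
        for x in range(lo, hi + 1):
            rec(j + 1, rem - x, acc + lchoose(col[j], x))

    rec(0, r1, base)
    return float(min(total, 1.0))


def _pairwise(values, labels, levels, family, q=None):
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a = values[labels == levels[i]]
            b = values[labels == levels[j]]
            if family == "anova":
                p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            d = cliffs_delta(a, b)
            rows.append(
                dict(group_a=levels[i], group_b=levels[j], p=p,
                     effect_size=d.estimate, magnitude=d.magnitude_label)
            )
    out = pd.DataFrame(rows)
    if q is not None and len(out):
        out["reject_fdr"] = bh_fdr(out["p"].to_numpy(), q)
    return out


def group_compare(
    data,
    labels: Sequence[str] | None = None,
    family: str = "anova",
    alpha: float = 0.05,
    fdr_q: float | None = None,
) -> dict:
    """Omnibus group comparison with pairwise follow-ups.

    ``family``: "anova" (one-way ANOVA, Welch-t follow-ups), "kruskal_wallis"
    (Kruskal-Wallis, rank-sum follow-ups), or "fisher_exact" (an r x c count
    table; pairwise 2x2 Fisher follow-ups).  Follow-ups run only when the
    omnibus test is significant at ``alpha``; when ``fdr_q`` is given the
    pairwise family is corrected by Benjamini-Hochberg.
    """
    if family == "fisher_exact":
        if labels is not None:
            raise ValueError("fisher_exact expects a count table, not labelled values")
        T = np.asarray(data, float)
        if T.ndim != 2:
            raise ValueError("fisher_exact requires a 2-D count table")
        p = _fisher_exact_rxc(T)
        v = cramers_v(T)
        result = dict(family=family, omnibus_p=p, effect_size=v.estimate,
                      magnitude=v.magnitude_label, pairwise=pd.DataFrame())
        if p < alpha and T.shape[0] > 2:
            rows = []
            for i in range(T.shape[0]):
                for j in range(i + 1, T.shape[0]):
                    pij = _fisher_exact_rxc(T[[i, j], :])
                    rows.append(dict(group_a=i, group_b=j, p=pij))
            pw = pd.DataFrame(rows)
            if fdr_q is not None:
                pw["reject_fdr"] = bh_fdr(pw["p"].to_numpy(), fdr_q)
            result["pairwise"] = pw
        return result
    values = np.asarray(data, float)
    if labels is None:
        raise ValueError(f"{family} requires group labels")
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    groups = [values[labels == lev] for lev in levels]
    if family == "anova":
        p = float(sps.f_oneway(*groups).pvalue)
    elif family == "kruskal_wallis":
        p = float(sps.kruskal(*groups).pvalue)
    else:
        raise ValueError(f"unknown family {family!r}")
    result = dict(family=family, omnibus_p=p, pairwise=pd.DataFrame())
    if p < alpha:
        result["pairwise"] = _pairwise(values, labels, levels, family, fdr_q)
    return result
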