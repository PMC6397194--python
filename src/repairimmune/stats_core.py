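"""Statistical primitives used across the pipeline.

Contract-tested wrappers and implementations of the analysis battery:
pooled two-proportion z-test, Student/Welch t-test, one-way ANOVA with
Tukey's multiple-comparison adjustment, Pearson correlation, Storey
q-value FDR estimation, multinomial logistic regression (Wald output),
and Kaplan–Meier / log-rank / univariate proportional-hazards survival
analysis.

Standard computations delegate to scipy, statsmodels and lifelines; the
two-proportion z, the single-λ Storey estimator and the Breslow-ties
univariate Cox solver are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "AnovaResult",
    "RegressionFit",
    "SurvivalResult",
    "two_proportion_z",
    "t_test",
    "anova_tukey",
    "pearson",
    "storey_q",
    "multinomial_logit",
    "km_logrank_hr",
]


@dataclass(frozen=True)
class TestResult:
    """A two-sided hypothesis test outcome."""

    statistic: float
    p: float
    df: float | tuple[float, float] | None = None
    estimate: float | None = None
    ci: tuple[float, float] | None = None


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled-variance z-test for two population proportions.

    z = (p1 − p2) / sqrt(p̂(1 − p̂)(1/n1 + 1/n2)) with p̂ the pooled
    proportion; two-sided normal p.  No continuity correction.  When the
    pooled proportion is 0 or 1 the statistic is undefined and reported
    as NaN.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    estimate = p1 - p2
    if pooled in (0.0, 1.0):
        return TestResult(statistic=float("nan"), p=float("nan"), estimate=estimate)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = estimate / se
    p = 2 * sps.norm.sf(abs(z))
    # CI for the difference uses the unpooled standard error
    se_u = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    ci = (estimate - 1.96 * se_u, estimate + 1.96 * se_u)
    return TestResult(statistic=float(z), p=float(p), estimate=estimate, ci=ci)


def t_test(a: Sequence[float], b: Sequence[float], welch: bool = False) -> TestResult:
    """Unpaired two-tailed Student's (pooled) or Welch's t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each arm needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    estimate = float(a.mean() - b.mean())
    df = float(res.df)
    if welch:
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    else:
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
        se = np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    tcrit = sps.t.ppf(0.975, df) if se > 0 else float("nan")
    ci = (estimate - tcrit * se, estimate + tcrit * se) if se > 0 else None
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), df=df, estimate=estimate, ci=ci)


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA with Tukey-adjusted pairwise comparisons."""

    f: float
    p: float
    df: tuple[float, float]
    pairwise: pd.DataFrame  # columns: group_a, group_b, meandiff, p_adj


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA; pairwise p from the studentized range.

    With two groups the Tukey-adjusted pairwise p equals the ANOVA p.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for n, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {n!r} has fewer than 2 values")
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(arr.size for arr in arrays)
    tukey = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "meandiff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(tukey.pvalue[i, j]),
                }
            )
    return AnovaResult(
        f=float(f),
        p=float(p),
        df=(float(k - 1), float(n_total - k)),
        pairwise=pd.DataFrame(rows),
    )


def pearson(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Pearson correlation with its t-based two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("Pearson correlation needs paired vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    res = sps.pearsonr(a, b)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), df=float(a.size - 2),
                      estimate=float(res.statistic))


def storey_q(p: Sequence[float], lam: float = 0.5, pi0_min_tests: int = 20) -> np.ndarray:
    """Storey q-values with the single-λ null-proportion estimator.

    π̂0 = min(1, #{p > λ} / ((1 − λ) m)); q-values are π̂0·m·p(i)/i with a
    running minimum applied from the largest p downward, so q is
    monotone in p and ≤ 1.  With π̂0 = 1 this reduces exactly to
    Benjamini–Hochberg adjusted p-values.

    The single-λ estimator is unstable for small batches (with few
    p-values, π̂0 can collapse to 0 by chance and declare everything
    significant), so for m < ``pi0_min_tests`` the estimator falls back
    to π̂0 = 1, i.e. plain Benjamini–Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("storey_q requires at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 <= lam < 1:
        raise ValueError("lambda must lie in [0, 1)")
    m = p.size
    if m < pi0_min_tests:
        pi0 = 1.0
    else:
        pi0 = min(1.0, np.sum(p > lam) / ((1.0 - lam) * m))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class RegressionFit:
    """Multinomial logistic regression output in Coef./SE/p form."""

    baseline: str
    levels: tuple[str, ...]  # non-baseline outcome levels
    coef: pd.DataFrame  # level × predictor
    se: pd.DataFrame
    p: pd.DataFrame
    converged: bool


def multinomial_logit(
    X: pd.DataFrame,
    y: Sequence[str],
    baseline: str,
    add_intercept: bool = True,
    maxiter: int = 200,
) -> RegressionFit:
    """Maximum-likelihood multinomial logistic regression.

    Coefficients describe log-odds of each non-baseline outcome level
    versus ``baseline``; standard errors come from the inverse observed
    information and p-values are two-sided Wald tests.  Non-convergence
    is flagged, never silent.
    """
    import statsmodels.api as sm

    y = pd.Series(list(y))
    levels = [lvl for lvl in pd.unique(y) if lvl != baseline]
    if baseline not in set(y):
        raise ValueError(f"baseline level {baseline!r} absent from outcomes")
    if not levels:
        raise ValueError("outcome has a single level; no contrast to fit")
    # statsmodels codes the first category as the reference
    cat = pd.Categorical(y, categories=[baseline] + sorted(levels))
    codes = pd.Series(cat.codes)
    if (codes == -1).any():
        raise ValueError("outcome contains labels outside the declared levels")
    design = sm.add_constant(X.reset_index(drop=True), has_constant="add") if add_intercept else X.reset_index(drop=True)
    # collinearity check
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError("design matrix is rank-deficient (perfectly collinear predictors)")
    model = sm.MNLogit(codes, design)
    fit = model.fit(disp=False, maxiter=maxiter)
    converged = bool(fit.mle_retvals.get("converged", False))
    level_names = [str(c) for c in cat.categories[1:]]
    coef = pd.DataFrame(fit.params.to_numpy().T, index=level_names, columns=design.columns)
    se = pd.DataFrame(fit.bse.to_numpy().T, index=level_names, columns=design.columns)
    pvals = pd.DataFrame(fit.pvalues.to_numpy().T, index=level_names, columns=design.columns)
    return RegressionFit(
        baseline=baseline,
        levels=tuple(level_names),
        coef=coef,
        se=se,
        p=pvals,
        converged=converged,
    )


@dataclass(frozen=True)
class SurvivalResult:
    """KM curves, log-rank test and univariate hazard ratio."""

    km_curves: dict  # group label -> survival-function DataFrame
    logrank_chi2: float
    logrank_p: float
    hr: float | None
    hr_ci: tuple[float, float] | None
    cox_beta: float | None
    cox_se: float | None


def _cox_breslow_univariate(
    time: np.ndarray, event: np.ndarray, x: np.ndarray, tol: float = 1e-10, maxiter: int = 50
) -> tuple[float, float]:
    """Newton–Raphson for a univariate Cox model with Breslow ties.

    Returns (beta_hat, se).  The Breslow partial log-likelihood is
    l(β) = Σ_events [β x_i − d_t · log Σ_{j in risk set} exp(β x_j)]
    summed over distinct event times t with d_t tied events.
    """
    order = np.argsort(-time, kind="mergesort")  # descending time
    t_sorted = time[order]
    e_sorted = event[order]
    x_sorted = x[order]
    beta = 0.0
    for _ in range(maxiter):
        exb = np.exp(beta * x_sorted)
        # cumulative risk-set sums walking from the largest time down
        s0 = np.cumsum(exb)
        s1 = np.cumsum(exb * x_sorted)
        s2 = np.cumsum(exb * x_sorted**2)
        # risk set at time t includes all with time >= t: with descending
        # order, that is the prefix up to the last index sharing time t
        _, inverse, counts = np.unique(-t_sorted, return_inverse=True, return_counts=True)
        last_idx = np.cumsum(counts) - 1
        idx = last_idx[inverse]
        grad = 0.0
        info = 0.0
        ev = e_sorted.astype(bool)
        if ev.any():
            S0 = s0[idx][ev]
            S1 = s1[idx][ev]
            S2 = s2[idx][ev]
            grad = float(np.sum(x_sorted[ev] - S1 / S0))
            info = float(np.sum(S2 / S0 - (S1 / S0) ** 2))
        if info <= 0:
            raise ValueError("Cox information matrix is singular (no usable events)")
        step = grad / info
        beta += step
        if abs(beta) > 30:
            raise ValueError("monotone partial likelihood (separation); hazard ratio unbounded")
        if abs(step) < tol:
            break
    exb = np.exp(beta * x_sorted)
    s0 = np.cumsum(exb)
    s1 = np.cumsum(exb * x_sorted)
    s2 = np.cumsum(exb * x_sorted**2)
    _, inverse, counts = np.unique(-t_sorted, return_inverse=True, return_counts=True)
    last_idx = np.cumsum(counts) - 1
    idx = last_idx[inverse]
    ev = e_sorted.astype(bool)
    S0, S1, S2 = s0[idx][ev], s1[idx][ev], s2[idx][ev]
    info = float(np.sum(S2 / S0 - (S1 / S0) ** 2))
    return float(beta), float(1.0 / np.sqrt(info))


def cox_breslow_loglik(time, event, x, beta: float) -> float:
    """Breslow partial log-likelihood at ``beta`` (for oracle checks)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for t in np.unique(time[event]):
        at_t = event & (time == t)
        risk = time >= t
        d = int(at_t.sum())
        ll += beta * x[at_t].sum() - d * np.log(np.sum(np.exp(beta * x[risk])))
    return float(ll)


def km_logrank_hr(
    time: Sequence[float],
    event: Sequence[bool],
    group: Sequence,
    fit_hr: bool = True,
) -> SurvivalResult:
    """Compare survival between two groups.

    Product-limit (Kaplan–Meier) curves per group, the standard log-rank
    test, and — when ``fit_hr`` — the hazard ratio of the second group
    level versus the first from a univariate proportional-hazards fit
    with Breslow tie handling, with CI = exp(β̂ ± 1.96·SE).  If either
    arm has no events the HR is reported as missing while the log-rank
    test is still computed.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    if np.any(time < 0):
        raise ValueError("survival times must be >= 0")
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(labels)}")
    mask0 = group == labels[0]
    if mask0.all() or (~mask0).all():
        raise ValueError("both groups must be non-empty")

    curves = {}
    for label in labels:
        m = group == label
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(label))
        curves[label] = kmf.survival_function_

    lr = logrank_test(time[mask0], time[~mask0], event[mask0], event[~mask0])
    chi2, p = float(lr.test_statistic), float(lr.p_value)

    hr = hr_ci = beta = se = None
    if fit_hr and event[mask0].any() and event[~mask0].any():
        x = (~mask0).astype(float)  # second level vs first
        try:
            beta, se = _cox_breslow_univariate(time, event.astype(int), x)
        except ValueError:
            beta = se = None  # separation or degenerate risk sets: HR missing
        if beta is not None:
            hr = float(np.exp(beta))
            hr_ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    return SurvivalResult(
        km_curves=curves,
        logrank_chi2=chi2,
        logrank_p=p,
        hr=hr,
        hr_ci=hr_ci,
        cox_beta=beta,
        cox_se=se,
    )
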