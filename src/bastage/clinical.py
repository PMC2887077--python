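"""Association of molecular groups with clinical covariates and outcome.

Covers the statistical toolkit used to test whether molecular staging of
biliary atresia livers (inflammation vs fibrosis) relates to clinical
presentation and two-year transplant-free survival: Fisher's exact test
and odds ratios for categorical covariates, Wilcoxon rank-sum and
Kruskal-Wallis for ordinal/continuous ones, Gaussian-kernel age
densities, Kaplan-Meier curves with the log-rank test, and binary
logistic regression for outcome ~ age (+ group) modelling.  All p-values
are two-sided.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger("bastage.clinical")


class ClinicalStatsError(ValueError):
    """Invalid input to a clinical-association routine."""


# ---------------------------------------------------------------------------
# categorical association


def _check_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ClinicalStatsError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ClinicalStatsError("contingency table cells must be nonnegative")
    if not np.allclose(t, np.round(t)):
        raise ClinicalStatsError("contingency table cells must be integers")
    if t.sum() < 1:
        raise ClinicalStatsError("contingency table total must be >= 1")
    return t.astype(int)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (rows=group, cols=outcome).

    The p-value sums the hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed that of the
    observed table.
    """
    t = _check_table(table)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


class OddsRatioResult(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    method: str


def odds_ratio_ci(
    table,
    method: Literal["conditional_exact", "woolf_haldane"] = "conditional_exact",
    confidence: float = 0.95,
) -> OddsRatioResult:
    """Odds ratio with confidence interval for a 2x2 table.

    ``conditional_exact`` (default) is the conditional maximum-likelihood
    estimate with the exact interval obtained by inverting the noncentral
    hypergeometric likelihood — appropriate for the small or empty cells
    typical of rare two-year outcomes.  ``woolf_haldane`` is the sample
    odds ratio ad/bc with the Woolf log-normal interval, adding 0.5 to
    every cell (Haldane) when any cell is zero.
    """
    t = _check_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ClinicalStatsError("odds ratio undefined: a full row or column is zero")
    if method == "woolf_haldane":
        tt = t.astype(float) + (0.5 if np.any(t == 0) else 0.0)
        or_ = (tt[0, 0] * tt[1, 1]) / (tt[0, 1] * tt[1, 0])
        z = stats.norm.ppf(0.5 + confidence / 2.0)
        half = z * np.sqrt(np.sum(1.0 / tt))
        lo, hi = np.exp(np.log(or_) - half), np.exp(np.log(or_) + half)
    elif method == "conditional_exact":
        res = stats.contingency.odds_ratio(t, kind="conditional")
        ci = res.confidence_interval(confidence_level=confidence)
        or_, lo, hi = res.statistic, ci.low, ci.high
    else:
        raise ClinicalStatsError(f"unknown odds-ratio method {method!r}")
    return OddsRatioResult(float(or_), float(lo), float(hi), method)


# ---------------------------------------------------------------------------
# rank tests


class RankTestResult(NamedTuple):
    statistic: float
    p: float


def _exact_ranksum_p(ranks: np.ndarray, n1: int, observed_w: float) -> float:
    """Exact two-sided rank-sum p by full enumeration (handles ties via midranks)."""
    n = ranks.size
    mu = n1 * (n + 1) / 2.0
    obs_dev = abs(observed_w - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= obs_dev - 1e-9:
            count += 1
        total += 1
    return count / total


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], continuity: bool = True
) -> RankTestResult:
    """Two-sample Wilcoxon rank-sum test, two-sided.

    The statistic W is the sum of the (mid)ranks of ``x`` in the pooled
    sample.  For small samples (n1 + n2 <= 12) the p-value is computed by
    exhaustive enumeration of rank assignments, which remains exact under
    ties; otherwise a normal approximation with tie-corrected variance
    and an optional 0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ClinicalStatsError("wilcoxon_rank_sum: empty input")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n2 = x.size, y.size
    n = n1 + n2
    w = float(ranks[:n1].sum())
    if n <= 12:
        return RankTestResult(w, _exact_ranksum_p(ranks, n1, w))
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return RankTestResult(w, 1.0)
    dev = w - mu
    if continuity:
        dev = np.sign(dev) * max(abs(dev) - 0.5, 0.0)
    z = dev / np.sqrt(var)
    return RankTestResult(w, float(min(1.0, 2.0 * stats.norm.sf(abs(z)))))


def kruskal_wallis(*groups: Sequence[float]) -> RankTestResult:
    """Kruskal-Wallis one-way ANOVA on ranks with tie correction.

    p from chi-square with k-1 degrees of freedom.  Degenerate input
    with every observation identical returns (H=0, p=1).
    """
    if len(groups) < 2:
        raise ClinicalStatsError("kruskal_wallis needs >=2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ClinicalStatsError("kruskal_wallis: empty group")
    if sum(a.size for a in arrays) < 3:
        raise ClinicalStatsError("kruskal_wallis needs total n >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return RankTestResult(0.0, 1.0)
    h, p = stats.kruskal(*arrays)
    return RankTestResult(float(h), float(p))


# ---------------------------------------------------------------------------
# age densities


@dataclass(frozen=True)
class AgeDensity:
    """Gaussian-kernel density of age at surgery on an explicit grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ClinicalStatsError("silverman bandwidth needs >=2 distinct values")
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(s for s in (sd, iqr / 1.34) if s > 0)
    return float(0.9 * spread * values.size ** (-0.2))


def age_density(
    ages: Sequence[float],
    bandwidth: "float | Literal['silverman']" = "silverman",
    grid_size: int = 512,
) -> AgeDensity:
    """Gaussian kernel density estimate of an age distribution.

    The evaluation grid spans the data range extended by four bandwidths
    on each side, so the density integrates to 1 within 1e-3.
    """
    a = np.asarray(ages, dtype=float)
    if a.size == 0:
        raise ClinicalStatsError("age_density: empty input")
    if bandwidth == "silverman":
        h = silverman_bandwidth(a)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ClinicalStatsError(f"bandwidth must be positive, got {h}")
    grid = np.linspace(a.min() - 4 * h, a.max() + 4 * h, grid_size)
    dens = np.mean(stats.norm.pdf(grid[:, None], loc=a[None, :], scale=h), axis=1)
    return AgeDensity(grid=grid, density=dens, bandwidth=h)


def compare_age_centers(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["wilcoxon", "permutation"] = "wilcoxon",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided p for equality of distribution centers.

    Default is the Wilcoxon rank-sum test with continuity correction (the
    same test applied to the age comparison in the association report); a
    seeded permutation test on the difference of medians is available.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ClinicalStatsError("compare_age_centers: empty input")
    if method == "wilcoxon":
        return wilcoxon_rank_sum(x, y, continuity=True).p
    if method != "permutation":
        raise ClinicalStatsError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    observed = abs(np.median(x) - np.median(y))
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = abs(np.median(perm[: x.size]) - np.median(perm[x.size :]))
        if stat >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit curve.

    ``times`` are the distinct observed times (events and censorings),
    with the number at risk, events, and the survival estimate
    S(t) = prod_{t_i <= t} (1 - d_i / n_i) at each.  Subjects censored at
    an event time remain at risk for those events (right-continuous
    convention); S(0) = 1.
    """

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        mask = self.times <= t
        return float(self.survival[mask][-1]) if mask.any() else 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator for one group."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ClinicalStatsError("km_estimate: no records")
    if t.size != e.size:
        raise ClinicalStatsError("times and events differ in length")
    if np.any(t < 0):
        raise ClinicalStatsError("negative survival time")
    if not set(np.unique(e)) <= {0, 1}:
        raise ClinicalStatsError("event flags must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    distinct = np.unique(t)
    table = kmf.event_table
    at_risk = table.loc[distinct, "at_risk"].to_numpy(dtype=int)
    d = table.loc[distinct, "observed"].to_numpy(dtype=int)
    surv = kmf.survival_function_at_times(distinct).to_numpy(dtype=float)
    return KMCurve(times=distinct, at_risk=at_risk, events=d, survival=surv)


class LogrankResult(NamedTuple):
    chi2: float
    p: float


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
) -> LogrankResult:
    """Two-group log-rank test: chi2 = (sum(O-E))^2 / sum(V), 1 df."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(list(map(str, groups)))
    if not (t.size == e.size == g.size) or t.size == 0:
        raise ClinicalStatsError("times, events and groups must be nonempty and aligned")
    labels = sorted(set(g))
    if len(labels) != 2:
        raise ClinicalStatsError(f"log-rank needs exactly two groups, got {labels}")
    if e.sum() == 0:
        logger.warning("log-rank: no events in either group; p = 1")
        return LogrankResult(0.0, 1.0)
    a, b = labels
    res = _ll_logrank(
        t[g == a], t[g == b], event_observed_A=e[g == a], event_observed_B=e[g == b]
    )
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def logrank_hazard_ratio(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
) -> float:
    """Pike estimate of the hazard ratio (group2 vs group1) from O/E counts.

    Walks the risk sets at each distinct event time to accumulate the
    observed and log-rank-expected events per group, then returns
    (O2/E2) / (O1/E1), where group1 is the lexicographically first label.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(list(map(str, groups)))
    labels = sorted(set(g))
    if len(labels) != 2:
        raise ClinicalStatsError(f"need exactly two groups, got {labels}")
    o = {lab: 0.0 for lab in labels}
    expected = {lab: 0.0 for lab in labels}
    for tau in np.unique(t[e == 1]):
        at_risk = t >= tau
        n = at_risk.sum()
        d = int(((t == tau) & (e == 1)).sum())
        for lab in labels:
            n_lab = (at_risk & (g == lab)).sum()
            d_lab = int(((t == tau) & (e == 1) & (g == lab)).sum())
            o[lab] += d_lab
            expected[lab] += d * n_lab / n
    a, b = labels
    if o[a] == 0 or o[b] == 0 or expected[a] == 0 or expected[b] == 0:
        raise ClinicalStatsError("hazard ratio undefined: a group has no events")
    return float((o[b] / expected[b]) / (o[a] / expected[a]))


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class LogisticFit:
    """Binary logistic regression fit (maximum likelihood, Newton/IRLS)."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    converged: bool
    separation: bool
    names: tuple[str, ...]


def logistic_fit(
    outcome: Sequence[int],
    covariates: np.ndarray,
    names: Sequence[str] | None = None,
    maxiter: int = 50,
) -> LogisticFit:
    """Fit outcome ~ covariates by maximum likelihood.

    ``covariates`` is the full design matrix including the intercept
    column.  Complete separation (fitted probabilities pinned at 0/1,
    diverging coefficients) is detected and flagged rather than raised;
    a rank-deficient design is an error naming the offending column.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim != 2:
        raise ClinicalStatsError("covariates must be a 2-D design matrix")
    n, p = X.shape
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    else:
        names = tuple(names)
        if len(names) != p:
            raise ClinicalStatsError("names length does not match design columns")
    if y.size != n:
        raise ClinicalStatsError("outcome length does not match design rows")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ClinicalStatsError("outcome must be binary 0/1")
    if n <= p:
        raise ClinicalStatsError(f"need n > {p} covariates, got n = {n}")
    if np.linalg.matrix_rank(X) < p:
        for j in range(1, p + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise ClinicalStatsError(
                    f"design matrix is rank-deficient at column {names[j - 1]!r}"
                )

    model = sm.Logit(y, X)
    model.raise_on_perfect_prediction = False
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(method="newton", maxiter=maxiter, disp=0)
        except Exception:  # singular Hessian under separation
            res = model.fit(method="bfgs", maxiter=200, disp=0)
    for w in caught:
        if "separation" in str(w.message).lower() or "Separation" in str(
            w.category.__name__
        ):
            separation = True
    params = np.asarray(res.params, dtype=float)
    fitted = model.predict(params)
    if np.any(fitted[y == 1] > 1 - 1e-10) and np.any(fitted[y == 0] < 1e-10):
        if np.max(np.abs(params[1:] if p > 1 else params)) > 20:
            separation = True
    converged = bool(res.mle_retvals.get("converged", False)) and not separation
    if separation:
        logger.warning("logistic_fit: complete separation detected; fit flagged")
    return LogisticFit(
        coefficients=params,
        standard_errors=np.asarray(res.bse, dtype=float),
        p_values=np.asarray(res.pvalues, dtype=float),
        converged=converged,
        separation=separation,
        names=names,
    )
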