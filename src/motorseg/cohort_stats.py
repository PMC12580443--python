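"""Nonparametric cohort inference.

Implements the inferential layer applied to per-subject medians: exact
binomial prevalence with a Clopper-Pearson interval, Kruskal-Wallis omnibus
tests with Dunn's pairwise follow-ups (Bonferroni-adjusted, z converted to
the effect size r = |z| / sqrt(n)), Mann-Whitney U for two-group contrasts,
Friedman's test with step-down homogeneous subsets for repeated ordinal
durations, and median/IQR/CV descriptives.

The nonparametric path is fixed by design for force measures; no normality
gating is performed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PrevalenceResult",
    "OmnibusResult",
    "PairwiseResult",
    "MannWhitneyResult",
    "FriedmanResult",
    "Descriptives",
    "prevalence_test",
    "kruskal_wallis",
    "dunn_pairwise_bonferroni",
    "effect_size_r",
    "mann_whitney",
    "friedman_chi2",
    "friedman_stepdown",
    "descriptives",
]


@dataclass(frozen=True)
class PrevalenceResult:
    k: int
    n: int
    phat: float
    p_two_sided: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.phat <= self.ci_high <= 1.0:
            raise ValueError("confidence bounds must bracket the estimate in [0, 1]")


@dataclass(frozen=True)
class OmnibusResult:
    H: float
    df: int
    p: float


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p_unadj: float
    p_adj: float
    r: float
    n_pair: int


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    z: float
    p: float
    r: float
    p_exact: float | None = None  # enumeration p, reported for small samples


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float
    n_rows: int
    n_dropped: int
    mean_ranks: tuple[float, ...]
    homogeneous_subsets: tuple[tuple[int, ...], ...] = ()


@dataclass(frozen=True)
class Descriptives:
    median: float
    iqr: float
    cv_percent: float | None  # None when the mean is zero


def prevalence_test(
    k: int, n: int, p0: float = 0.5, alpha: float = 0.05, method: str = "double-tail"
) -> PrevalenceResult:
    """Exact binomial test of a proportion with Clopper-Pearson interval.

    The default two-sided p doubles the smaller tail,
    ``min(1, 2*min(P(X<=k), P(X>=k)))`` under Binomial(n, p0); the
    minimum-likelihood-sum alternative is available as ``method='minlike'``.
    The 1-alpha interval uses the inverse incomplete-beta bounds
    (``ci_low = 0`` when k = 0, ``ci_high = 1`` when k = n).
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if method == "double-tail":
        lower = stats.binom.cdf(k, n, p0)
        upper = stats.binom.sf(k - 1, n, p0)
        p = min(1.0, 2.0 * min(lower, upper))
    elif method == "minlike":
        p = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    ci_low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    ci_high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return PrevalenceResult(
        k=k, n=n, phat=k / n, p_two_sided=float(p), ci_low=ci_low, ci_high=ci_high
    )


def kruskal_wallis(groups: list) -> OmnibusResult:
    """Kruskal-Wallis H with midrank tie correction, chi-square reference.

    All pooled values identical is a degenerate case reported as H = 0,
    p = 1 (no evidence of a group difference).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least three observations in total")
    if np.all(pooled == pooled[0]):
        return OmnibusResult(H=0.0, df=len(groups) - 1, p=1.0)
    H, p = stats.kruskal(*groups)
    return OmnibusResult(H=float(H), df=len(groups) - 1, p=float(p))


def _tie_term(pooled: np.ndarray) -> float:
    """sum(t^3 - t) over tied groups in the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def effect_size_r(z: float, n_pair: int) -> float:
    """Effect size r = |z| / sqrt(n), n the summed size of the two groups."""
    if n_pair < 2:
        raise ValueError("n_pair must be at least 2")
    return abs(z) / np.sqrt(n_pair)


def dunn_pairwise_bonferroni(groups: list, labels: list[str]) -> list[PairwiseResult]:
    """Dunn's pairwise z tests on pooled midranks, Bonferroni-adjusted.

    For groups i, j with mean pooled ranks Rbar_i, Rbar_j:

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    with T = sum(t^3 - t) over ties.  Unadjusted p values are two-sided
    normal tails, multiplied by the number of contrasts m = g(g-1)/2 and
    capped at 1.  Each contrast carries r = |z| / sqrt(n_i + n_j).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) != len(labels):
        raise ValueError("labels must match groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [float(np.mean(ranks[bounds[i] : bounds[i + 1]])) for i in range(len(groups))]
    tie_adj = _tie_term(pooled) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_adj
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_un = 2.0 * stats.norm.sf(abs(z))
        n_pair = sizes[i] + sizes[j]
        out.append(
            PairwiseResult(
                pair=(labels[i], labels[j]),
                z=float(z),
                p_unadj=float(min(1.0, p_un)),
                p_adj=float(min(1.0, p_un * m)),
                r=float(effect_size_r(z, n_pair)),
                n_pair=n_pair,
            )
        )
    return out


def _mw_exact_p(x: np.ndarray, y: np.ndarray, U: float) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group labelings."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    ranks = stats.rankdata(pooled)
    idx = range(pooled.size)
    u_obs = min(U, n1 * y.size - U)
    count = total = 0
    for comb in itertools.combinations(idx, n1):
        r1 = ranks[list(comb)].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        u_low = min(u, n1 * y.size - u)
        total += 1
        if u_low <= u_obs + 1e-12:
            count += 1
    return count / total


def mann_whitney(g1, g2) -> MannWhitneyResult:
    """Mann-Whitney U with tie-corrected normal z and two-sided p.

    For combined samples of 12 or fewer an exact enumeration p over all
    labelings is reported alongside the normal approximation.
    """
    x = np.asarray(g1, dtype=float)
    y = np.asarray(g2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    U = r1 - n1 * (n1 + 1) / 2.0
    N = n1 + n2
    mu = n1 * n2 / 2.0
    tie = _tie_term(pooled) / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie)
    z = 0.0 if var <= 0 else (U - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z)) if var > 0 else 1.0
    p_exact = _mw_exact_p(x, y, U) if N <= 12 else None
    return MannWhitneyResult(
        U=float(U),
        z=float(z),
        p=float(min(1.0, p)),
        r=float(effect_size_r(z, N)),
        p_exact=p_exact,
    )


def friedman_chi2(matrix) -> FriedmanResult:
    """Friedman's rank test across conditions with within-row midranks.

    Tie-corrected statistic on an n-rows-by-k-conditions matrix:

        chi2 = [12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1)] / C,
        C = 1 - sum(t^3 - t) / (n k (k^2 - 1)),

    referred to chi-square with k - 1 degrees of freedom.  Works for k = 2
    (where it reduces to the sign-test statistic on within-pair orderings).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows and >= 2 conditions")
    n, k = X.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    R = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts.astype(float) ** 3 - counts))
    C = 1.0 - ties / (n * k * (k * k - 1))
    chi2 = 0.0 if C <= 0 else stat / C
    p = 1.0 if chi2 == 0 else float(stats.chi2.sf(chi2, k - 1))
    return FriedmanResult(
        chi2=float(chi2),
        df=k - 1,
        p=p,
        n_rows=n,
        n_dropped=0,
        mean_ranks=tuple(float(r) for r in ranks.mean(axis=0)),
    )


def friedman_stepdown(matrix, alpha: float = 0.05) -> FriedmanResult:
    """Friedman's test plus step-down homogeneous subsets.

    Rows containing missing values are dropped (complete-case; the number
    dropped is recorded).  Conditions are ordered by mean rank; every
    maximal contiguous run of conditions in that order whose restricted
    Friedman test is nonsignificant (p > alpha) forms a homogeneous subset,
    so subsets may overlap.  Subset members are reported as 0-based column
    indices of the input matrix.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 conditions")
    complete = np.all(np.isfinite(X), axis=1)
    n_dropped = int(X.shape[0] - complete.sum())
    X = X[complete]
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 complete rows")
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} incomplete rows", stacklevel=2)
    base = friedman_chi2(X)
    k = X.shape[1]
    order = [int(i) for i in np.argsort(base.mean_ranks, kind="stable")]

    def run_ok(cols: list[int]) -> bool:
        if len(cols) == 1:
            return True
        return friedman_chi2(X[:, cols]).p > alpha

    runs: list[tuple[int, ...]] = []
    for i in range(k):
        j = i
        while j + 1 < k and run_ok([order[c] for c in range(i, j + 2)]):
            j += 1
        runs.append(tuple(order[c] for c in range(i, j + 1)))
    # keep maximal runs only (drop runs whose members are a subset of another)
    subsets = [
        r
        for r in runs
        if not any(set(r) < set(other) for other in runs if other != r)
    ]
    seen: list[tuple[int, ...]] = []
    for r in subsets:
        if r not in seen:
            seen.append(r)
    return FriedmanResult(
        chi2=base.chi2,
        df=base.df,
        p=base.p,
        n_rows=X.shape[0],
        n_dropped=n_dropped,
        mean_ranks=base.mean_ranks,
        homogeneous_subsets=tuple(seen),
    )


def descriptives(values) -> Descriptives:
    """Median, IQR (Q3 - Q1, linear-interpolation quantiles) and CV.

    CV is 100 * sample SD (n-1 denominator) / mean, undefined (None) when
    the mean is zero; it requires at least two values.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("descriptives require finite values")
    q1, q3 = np.percentile(x, [25, 75])
    cv: float | None
    if x.size < 2:
        cv = None
    else:
        mean = float(np.mean(x))
        if mean == 0:
            warnings.warn("CV undefined for zero-mean data", stacklevel=2)
            cv = None
        else:
            cv = 100.0 * float(np.std(x, ddof=1)) / mean
    return Descriptives(median=float(np.median(x)), iqr=float(q3 - q1), cv_percent=cv)
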