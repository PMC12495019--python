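"""Normality-gated descriptive and inferential statistics with effect sizes.

Small-sample biology data cannot be assumed Gaussian, so every sample is
formally tested with the Shapiro-Wilk test at alpha = 0.05 and the analysis
branches accordingly: parametric (Student's t for one-sample and paired
designs, Welch's unequal-variance t for unpaired) with Cohen's d / d' as
effect sizes, or non-parametric (Wilcoxon signed-rank for one-sample and
paired, Wilcoxon rank-sum for unpaired) with the probability of superiority
as effect size.  All p-values are two-sided.

Effect-size conventions
-----------------------
* one-sample d = (mean - mu0) / SD.
* paired d = mean(diff) / SD(diff); paired d' = mean(diff) / pooled SD of
  the two samples (a standardizer insensitive to the pairing correlation).
* unpaired d = (m1 - m2) / pooled SD; unpaired d' uses the average-variance
  standardizer sqrt((s1^2 + s2^2) / 2), natural next to Welch's test.
* probability of superiority = P(X1 > X2) + 0.5 P(X1 = X2), i.e. the
  rank-sum U statistic divided by n1*n2 with tie halving; against a
  reference value mu0 it is the tie-halved fraction of the sample above mu0.

Positive d means the first argument's location exceeds the second's (or
mu0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA_NORMALITY = 0.05


@dataclass
class SampleDescriptor:
    n: int
    mean: float
    sd: float
    ci_mean: tuple[float, float]
    shapiro_p: float
    is_normal: bool
    median: float | None = None
    iqi: tuple[float, float] | None = None
    ci_median: tuple[float, float] | None = None


@dataclass
class ComparisonResult:
    design: str
    test_used: str
    statistic: float
    p: float
    n: tuple[int, ...]
    is_normal: bool
    cohens_d: float | None = None
    cohens_d_prime: float | None = None
    prob_superiority: float | None = None
    degenerate: bool = False


def _check_sample(x, name: str = "sample") -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError(f"{name} needs at least 3 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def shapiro_normal(x: np.ndarray) -> tuple[bool, float]:
    """Shapiro-Wilk normality call at alpha = 0.05.

    Constant samples are trivially non-normal (the test is undefined there).
    """
    if np.ptp(x) == 0:
        return False, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(sps.shapiro(x).pvalue)
    return p >= ALPHA_NORMALITY, p


def median_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI for the median from binomial order statistics.

    The interval (x_(j+1), x_(k)) with j = B^-1(alpha/2; n, 1/2) and
    k = n - j has coverage >= level for any continuous distribution.
    """
    xs = np.sort(x)
    n = xs.size
    alpha = 1.0 - level
    # smallest m with P(Bin(n, 1/2) <= m) >= alpha/2, so P(Bin < m) <= alpha/2
    m = int(sps.binom.ppf(alpha / 2.0, n, 0.5))
    lo = xs[max(m - 1, 0)]  # order statistic x_(m), 1-based
    hi = xs[min(n - m, n - 1)]  # x_(n + 1 - m)
    return float(lo), float(hi)


def describe(sample) -> SampleDescriptor:
    """Descriptive statistics with a formal normality call.

    Mean, sample SD (n-1) and the t-based 95% CI of the mean are always
    reported; when Shapiro-Wilk rejects normality the median, interquartile
    interval and order-statistic CI of the median are added.
    """
    x = _check_sample(sample)
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd > 0:
        half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    else:
        half = 0.0
    is_normal, p_sw = shapiro_normal(x)
    desc = SampleDescriptor(
        n=n,
        mean=mean,
        sd=sd,
        ci_mean=(mean - half, mean + half),
        shapiro_p=p_sw,
        is_normal=is_normal,
    )
    if not is_normal:
        desc.median = float(np.median(x))
        desc.iqi = (float(np.percentile(x, 25)), float(np.percentile(x, 75)))
        desc.ci_median = median_ci(x)
    return desc


def prob_superiority(a: np.ndarray, b: np.ndarray) -> float:
    """P(a > b) + 0.5 P(a = b) over all cross pairs (tie-halved U/(n1*n2))."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float(((a > b).sum() + 0.5 * (a == b).sum()) / (a.size * b.size))


def _cohens_d_one_sample(x: np.ndarray, mu0: float) -> float:
    sd = x.std(ddof=1)
    return float((x.mean() - mu0) / sd) if sd > 0 else float("nan")


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    return float(
        np.sqrt(
            ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        )
    )


def compare(
    a,
    b=None,
    mu0: float | None = None,
    design: str = "unpaired",
    branch: str | None = None,
) -> ComparisonResult:
    """Normality-gated two-sided comparison.

    design='one_sample' tests ``a`` against ``mu0``; 'paired' gates on the
    pairwise differences; 'unpaired' requires both groups to pass the
    normality test for the parametric branch.  ``branch`` overrides the
    normality gate with 'parametric' or 'nonparametric' when the analyst
    has external grounds for the choice.
    """
    if branch not in (None, "parametric", "nonparametric"):
        raise ValueError("branch must be None, 'parametric' or 'nonparametric'")
    if design == "one_sample":
        return _compare_one_sample(_check_sample(a, "a"), mu0, branch)
    if design == "paired":
        x = _check_sample(a, "a")
        y = _check_sample(b, "b")
        if x.size != y.size:
            raise ValueError("paired design requires equal lengths")
        return _compare_paired(x, y, branch)
    if design == "unpaired":
        return _compare_unpaired(
            _check_sample(a, "a"), _check_sample(b, "b"), branch
        )
    raise ValueError(f"unknown design {design!r}")


def _compare_one_sample(
    x: np.ndarray, mu0: float | None, branch: str | None = None
) -> ComparisonResult:
    if mu0 is None:
        raise ValueError("one_sample design requires mu0")
    diffs = x - mu0
    if np.ptp(x) == 0:
        equal = float(x[0]) == float(mu0)
        return ComparisonResult(
            design="one_sample",
            test_used="degenerate (constant sample)",
            statistic=0.0,
            p=1.0 if equal else 0.0,
            n=(x.size,),
            is_normal=False,
            cohens_d=0.0 if equal else float("inf") * np.sign(diffs[0]),
            prob_superiority=prob_superiority(x, np.array([mu0])),
            degenerate=True,
        )
    is_normal, _ = shapiro_normal(x)
    if branch is not None:
        is_normal = branch == "parametric"
    ps = prob_superiority(x, np.array([mu0]))
    if is_normal:
        res = sps.ttest_1samp(x, mu0)
        return ComparisonResult(
            design="one_sample",
            test_used="one-sample Student's t",
            statistic=float(res.statistic),
            p=float(res.pvalue),
            n=(x.size,),
            is_normal=True,
            cohens_d=_cohens_d_one_sample(x, mu0),
            prob_superiority=ps,
        )
    res = sps.wilcoxon(diffs, zero_method="wilcox")
    return ComparisonResult(
        design="one_sample",
        test_used="Wilcoxon signed-rank",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n=(x.size,),
        is_normal=False,
        cohens_d=_cohens_d_one_sample(x, mu0),
        prob_superiority=ps,
    )


def _compare_paired(
    x: np.ndarray, y: np.ndarray, branch: str | None = None
) -> ComparisonResult:
    d = x - y
    if np.ptp(d) == 0:
        equal = d[0] == 0
        return ComparisonResult(
            design="paired",
            test_used="degenerate (constant differences)",
            statistic=0.0,
            p=1.0 if equal else 0.0,
            n=(x.size, y.size),
            is_normal=False,
            cohens_d=0.0 if equal else float("inf") * np.sign(d[0]),
            cohens_d_prime=0.0 if equal else None,
            prob_superiority=prob_superiority(x, y),
            degenerate=True,
        )
    is_normal, _ = shapiro_normal(d)
    if branch is not None:
        is_normal = branch == "parametric"
    d_prime_sd = _pooled_sd(x, y)
    d_prime = float(d.mean() / d_prime_sd) if d_prime_sd > 0 else float("nan")
    if is_normal:
        res = sps.ttest_rel(x, y)
        return ComparisonResult(
            design="paired",
            test_used="paired Student's t",
            statistic=float(res.statistic),
            p=float(res.pvalue),
            n=(x.size, y.size),
            is_normal=True,
            cohens_d=float(d.mean() / d.std(ddof=1)),
            cohens_d_prime=d_prime,
            prob_superiority=prob_superiority(x, y),
        )
    res = sps.wilcoxon(d, zero_method="wilcox")
    return ComparisonResult(
        design="paired",
        test_used="Wilcoxon signed-rank",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n=(x.size, y.size),
        is_normal=False,
        cohens_d=float(d.mean() / d.std(ddof=1)),
        cohens_d_prime=d_prime,
        prob_superiority=prob_superiority(x, y),
    )


def _compare_unpaired(
    a: np.ndarray, b: np.ndarray, branch: str | None = None
) -> ComparisonResult:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        equal = a[0] == b[0]
        return ComparisonResult(
            design="unpaired",
            test_used="degenerate (both groups constant)",
            statistic=0.0,
            p=1.0 if equal else 0.0,
            n=(a.size, b.size),
            is_normal=False,
            prob_superiority=prob_superiority(a, b),
            degenerate=True,
        )
    norm_a, _ = shapiro_normal(a)
    norm_b, _ = shapiro_normal(b)
    is_normal = norm_a and norm_b
    if branch is not None:
        is_normal = branch == "parametric"
    ps = prob_superiority(a, b)
    if is_normal:
        res = sps.ttest_ind(a, b, equal_var=False)  # Welch
        pooled = _pooled_sd(a, b)
        avg_var = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        diff = a.mean() - b.mean()
        return ComparisonResult(
            design="unpaired",
            test_used="Welch's t",
            statistic=float(res.statistic),
            p=float(res.pvalue),
            n=(a.size, b.size),
            is_normal=True,
            cohens_d=float(diff / pooled) if pooled > 0 else float("nan"),
            cohens_d_prime=float(diff / avg_var) if avg_var > 0 else float("nan"),
            prob_superiority=ps,
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(
        design="unpaired",
        test_used="Wilcoxon rank-sum (Mann-Whitney U)",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n=(a.size, b.size),
        is_normal=False,
        prob_superiority=ps,
    )
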