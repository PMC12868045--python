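"""Group-comparison statistics: normality screening, all-pairs t-tests with
Bonferroni correction, effect sizes, and a-priori sample-size computation.

The battery mirrors standard practice in clinical kinematics studies: each
parameter's per-subject values are screened for normality with a
Kolmogorov-Smirnov test, every unordered pair of groups is compared with a
two-sample t-test (five groups give 10 pairs), and the resulting p-values are
Bonferroni-corrected within the parameter's family of 10 tests.

Effect sizes use Cohen's d with the balanced-design pooled SD,
``d = (m1 - m2) / sqrt((sd1^2 + sd2^2) / 2)``, and a-priori sample sizes are
the smallest per-group n at which a two-sample t-test with noncentrality
``d * sqrt(n / 2)`` and ``2n - 2`` degrees of freedom reaches the requested
power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, SampleSizeError, ValidationError


@dataclass(frozen=True)
class GroupComparison:
    """One pairwise two-sample t-test, corrected within its family."""

    pair: tuple[str, str]
    parameter: str
    n1: int
    n2: int
    t: float
    df: float
    p_raw: float
    p_adj: float
    d: float
    significant: bool


def ks_normality(sample: Sequence[float], lilliefors: bool = False) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality screen of a sample.

    By default the sample is tested against a normal distribution with the
    sample's own mean and SD and the classical KS p-value is returned (a
    conservative but widely used practice). With ``lilliefors=True`` the
    parameter-estimation is accounted for via the Lilliefors test, which has
    proper size and much better power against non-normal alternatives.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise SampleSizeError(f"normality test needs at least 4 observations, got {x.size}")
    sd = float(np.std(x, ddof=1))
    if sd < 1e-12:
        raise ValidationError("sample is constant (SD = 0); normality test undefined")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return float(stat), float(p)
    res = stats.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``, order preserved."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ParameterError(
            f"family size m={m} is smaller than the number of p-values {len(p_values)}"
        )
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ParameterError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Cohen's d with the balanced pooled SD ``sqrt((sd1^2 + sd2^2) / 2)``."""
    if sd1 <= 0 or sd2 <= 0:
        raise ParameterError("standard deviations must be positive")
    return (mean1 - mean2) / np.sqrt((sd1**2 + sd2**2) / 2.0)


def cohens_d_sample(x1: Sequence[float], x2: Sequence[float]) -> float:
    """Cohen's d from two samples (sample means and ddof=1 SDs)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return cohens_d(
        float(np.mean(x1)), float(np.std(x1, ddof=1)),
        float(np.mean(x2)), float(np.std(x2, ddof=1)),
    )


def pairwise_ttests(
    groups: Mapping[str, Sequence[float]],
    parameter: str = "",
    alpha: float = 0.05,
    equal_var: bool = True,
    m: int | None = None,
) -> list[GroupComparison]:
    """All-pairs two-sample t-tests across groups, Bonferroni-corrected.

    Groups with fewer than 2 subjects are excluded with a warning, and the
    correction family shrinks accordingly. ``equal_var=False`` selects the
    Welch variant. ``m`` overrides the family size (defaults to the number of
    pairs actually tested).
    """
    usable: dict[str, np.ndarray] = {}
    for g, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        if len(x) < 2:
            warnings.warn(
                f"group {g!r} has {len(x)} subject(s) and is excluded from testing",
                stacklevel=2,
            )
            continue
        usable[g] = x
    if len(usable) < 2:
        raise SampleSizeError("need at least 2 groups with >= 2 subjects each")
    pairs = list(combinations(usable.keys(), 2))
    family = m if m is not None else len(pairs)
    out: list[GroupComparison] = []
    for g1, g2 in pairs:
        x1, x2 = usable[g1], usable[g2]
        res = stats.ttest_ind(x1, x2, equal_var=equal_var)
        if equal_var:
            df = len(x1) + len(x2) - 2
        else:
            df = float(res.df)
        p_adj = bonferroni([float(res.pvalue)], family)[0]
        out.append(
            GroupComparison(
                pair=(g1, g2),
                parameter=parameter,
                n1=len(x1),
                n2=len(x2),
                t=float(res.statistic),
                df=float(df),
                p_raw=float(res.pvalue),
                p_adj=p_adj,
                d=cohens_d_sample(x1, x2),
                significant=bool(p_adj < alpha),
            )
        )
    return out


def ttest_power(d: float, n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of a two-sample t-test at effect size ``d`` and ``n`` per group.

    Uses the noncentral t distribution with noncentrality ``d * sqrt(n/2)``
    and ``2n - 2`` degrees of freedom.
    """
    if n < 2:
        raise ParameterError(f"n per group must be >= 2, got {n}")
    if tails not in (1, 2):
        raise ParameterError(f"tails must be 1 or 2, got {tails}")
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    df = 2 * n - 2
    ncp = abs(d) * np.sqrt(n / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / tails, df)
    power = stats.nct.sf(t_crit, df, ncp)
    if tails == 2:
        power += stats.nct.cdf(-t_crit, df, ncp)
    return float(power)


def required_sample_size(
    d: float, alpha: float = 0.05, power: float = 0.95, tails: int = 2
) -> int:
    """Smallest per-group n at which the two-sample t-test reaches ``power``.

    Monotone search: doubling until the target power is reached, then binary
    search for the smallest sufficient n (>= 2).
    """
    if d == 0:
        raise ParameterError("effect size d = 0: required sample size diverges")
    if not (0.0 < power < 1.0):
        raise ParameterError(f"power must be in (0, 1), got {power}")
    lo, hi = 2, 2
    while ttest_power(d, hi, alpha, tails) < power:
        lo = hi
        hi *= 2
        if hi > 10_000_000:
            raise ParameterError(f"required n exceeds 1e7 for d={d}")
    while lo < hi:
        mid = (lo + hi) // 2
        if ttest_power(d, mid, alpha, tails) >= power:
            hi = mid
        else:
            lo = mid + 1
    return hi
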