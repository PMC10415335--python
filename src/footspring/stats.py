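"""Group-comparison statistics.

The routing mirrors the study procedure: each parameter is compared between
the two sex groups with a two-sided equal-variance t-test when both samples
pass a Kolmogorov-Smirnov normality check (Lilliefors variant, since the
normal parameters are estimated from the sample), and with a two-sided
Wilcoxon-Mann-Whitney rank-sum test otherwise.  Tests run at alpha = 0.05;
the five-slip PA family additionally applies a Bonferroni correction with
the adjusted threshold p < 0.01 (= 0.05 / 5, strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ComparisonResult",
    "normality_test",
    "compare_groups",
    "bonferroni_family",
    "summarize",
    "type_i_error_rate",
]

PA_FAMILY_SIZE = 5


@dataclass
class ComparisonResult:
    parameter: str
    event: str | None
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test: str  # "t" | "rank-sum"
    statistic: float
    p_value: float
    alpha: float = 0.05
    significant: bool = field(init=False)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.significant = self.p_value < self.alpha


def normality_test(sample, pvalmethod: str = "table") -> float:
    """Lilliefors-corrected KS p-value against a fitted normal.

    The naive one-sample KS test assumes fully specified parameters; with
    mean/SD estimated from the sample the Lilliefors correction is the
    appropriate variant.  Returns the p-value; raises for n < 3 and returns
    0.0 for a degenerate (zero-variance) sample, which then routes to the
    rank-sum branch.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError(f"normality test needs n >= 3, got {x.size}")
    if np.std(x, ddof=1) == 0.0:
        return 0.0
    if x.size == 3:
        # the Lilliefors reference table starts at n = 4; fall back to the
        # naive KS statistic against the fitted normal for this corner
        _, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return float(p)
    _, p = lilliefors(x, dist="norm", pvalmethod=pvalmethod)
    return float(p)


def _rank_sum(a: np.ndarray, b: np.ndarray):
    """Wilcoxon-Mann-Whitney: exact for small tie-free samples, otherwise
    the tie-corrected normal approximation with continuity correction."""
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(a), len(b)) <= 8
    method = "exact" if (small and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(a, b, alpha: float = 0.05, parameter: str = "",
                   event: str | None = None, equal_var: bool = True) -> ComparisonResult:
    """Compare two samples with the normality-routed two-sided test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("both samples need n >= 3")
    normal = normality_test(a) > 0.05 and normality_test(b) > 0.05
    if normal:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test, stat, p = "t", float(res.statistic), float(res.pvalue)
    else:
        test = "rank-sum"
        stat, p = _rank_sum(a, b)
    return ComparisonResult(
        parameter=parameter, event=event,
        mean_a=float(np.mean(a)), sd_a=float(np.std(a, ddof=1)), n_a=int(a.size),
        mean_b=float(np.mean(b)), sd_b=float(np.std(b, ddof=1)), n_b=int(b.size),
        test=test, statistic=stat, p_value=min(max(p, 0.0), 1.0), alpha=alpha,
    )


def bonferroni_family(pvals, alpha: float = 0.05) -> list:
    """Family-wise decisions at the Bonferroni-adjusted threshold.

    For the five-slip PA family the threshold is alpha / 5 = 0.01 with
    strict inequality (p = 0.01 exactly is not significant).  Other family
    sizes generalize to alpha / m with a warning.
    """
    p = [float(v) for v in pvals]
    m = len(p)
    if m != PA_FAMILY_SIZE:
        warnings.warn(
            f"expected the {PA_FAMILY_SIZE}-member PA family, got {m}; "
            f"using alpha/{m}", stacklevel=2,
        )
    if m == 0:
        return []
    threshold = alpha / m
    return [v < threshold for v in p]


def summarize(sample):
    """Arithmetic mean and sample SD (n-1 denominator)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("summary needs n >= 2 for the sample SD")
    return float(np.mean(x)), float(np.std(x, ddof=1))


def type_i_error_rate(n_a: int = 9, n_b: int = 10, reps: int = 10_000,
                      alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I error of the routed procedure under a shared normal null."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        a = rng.standard_normal(n_a)
        b = rng.standard_normal(n_b)
        if compare_groups(a, b, alpha=alpha).significant:
            hits += 1
    return hits / reps
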