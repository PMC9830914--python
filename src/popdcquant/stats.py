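"""Control-median normalization, median CIs and the study's hypothesis tests.

Per-fiber and per-cell intensity ratios are strongly right-skewed, so the
whole layer is nonparametric where the study is: values are expressed
relative to the matched control median (control group == 1 by construction),
summarized by medians with distribution-free 95% confidence intervals, and
compared with Mann-Whitney (two groups), Kruskal-Wallis + Dunn (many groups,
rank-based) or one-way ANOVA + Dunnett (many-to-one, as used for per-image
BiFC means). All tests are two-sided; Dunn p-values are Holm-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class NormalizationError(ValueError):
    """Control values unusable for median normalization."""


@dataclass
class GroupSummary:
    """Normalized median and 95% CI for one group."""

    label: str
    n: int
    median_normalized: float
    ci_low: float
    ci_high: float


@dataclass
class ComparisonResult:
    """Outcome of one hypothesis test, with per-comparison adjusted p-values."""

    test: str
    statistic: float
    p_value: float
    comparisons: list[str] = field(default_factory=list)
    raw_p: list[float] = field(default_factory=list)
    adjusted_p: list[float] = field(default_factory=list)
    statistics: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def normalize_to_control(values, control_values) -> np.ndarray:
    """Divide ``values`` by the control median (control median maps to 1)."""
    control = np.asarray(control_values, dtype=float)
    control = control[np.isfinite(control)]
    if control.size == 0:
        raise NormalizationError("control group is empty")
    m = float(np.median(control))
    if m <= 0:
        raise NormalizationError(f"control median must be > 0, got {m}")
    return np.asarray(values, dtype=float) / m


def median_ci(
    values,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, float]:
    """Median with a distribution-free confidence interval.

    For n >= 6 the interval interpolates between the two adjacent binomial
    order-statistic intervals (Hettmansperger & Sheather), giving
    distribution-free coverage close to nominal rather than the conservative
    overshoot of the plain order-statistic interval. For n < 6 a seeded
    percentile bootstrap (2000 resamples) is used instead, with a warning
    that the interval is wide.
    """
    x = np.sort(np.asarray(values, dtype=float))
    x = x[np.isfinite(x)]
    n = x.size
    if n == 0:
        raise ValueError("median_ci needs at least one finite value")
    med = float(np.median(x))
    alpha = 1.0 - level
    if n >= 6:
        # largest d with two-sided coverage gamma_d >= level
        d = int(sps.binom.ppf(alpha / 2, n, 0.5))
        while d > 0 and sps.binom.cdf(d - 1, n, 0.5) > alpha / 2:
            d -= 1
        d = max(d, 1)
        gamma_d = 1.0 - 2.0 * sps.binom.cdf(d - 1, n, 0.5)
        gamma_d1 = 1.0 - 2.0 * sps.binom.cdf(d, n, 0.5) if d < n - d else gamma_d
        if gamma_d1 >= level or gamma_d <= gamma_d1:
            lam = 0.0
        else:
            frac = (gamma_d - level) / (gamma_d - gamma_d1)
            lam = (n - d) * frac / (d + (n - 2 * d) * frac)
        lo = (1 - lam) * x[d - 1] + lam * x[d]
        hi = (1 - lam) * x[n - d] + lam * x[n - d - 1]
        return med, float(lo), float(hi)
    import warnings

    warnings.warn(f"n={n} < 6: bootstrap median CI is wide", stacklevel=2)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    boots = np.median(rng.choice(x, size=(2000, n), replace=True), axis=1)
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return med, float(lo), float(hi)


def summarize_group(
    label: str, values, control_values=None, level: float = 0.95
) -> GroupSummary:
    """Control-normalize (optional) and summarize one group."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if control_values is not None:
        vals = normalize_to_control(vals, control_values)
    med, lo, hi = median_ci(vals, level=level)
    return GroupSummary(label=label, n=vals.size, median_normalized=med, ci_low=lo, ci_high=hi)


def mann_whitney(a, b) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact p when both groups have <= 20 observations and no cross-group
    ties, normal approximation with tie correction otherwise. Fully tied
    degenerate data returns p = 1 with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("mann_whitney needs >= 3 observations per group")
    flags: list[str] = []
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return ComparisonResult(
            test="mann_whitney",
            statistic=float(a.size * b.size / 2),
            p_value=1.0,
            flags=["degenerate_all_tied"],
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        test="mann_whitney", statistic=float(res.statistic), p_value=float(res.pvalue), flags=flags
    )


def _dunn_z(groups: dict[str, np.ndarray], pair: tuple[str, str]) -> float:
    """Dunn's rank z statistic with tie correction for one pair."""
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks = {}
    start = 0
    for k in labels:
        n_k = groups[k].size
        mean_ranks[k] = ranks[start : start + n_k].mean()
        start += n_k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    i, j = pair
    se = np.sqrt(var_unit * (1.0 / groups[i].size + 1.0 / groups[j].size))
    if se == 0:
        return 0.0
    return float((mean_ranks[i] - mean_ranks[j]) / se)


def kruskal_dunn(
    groups: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]] | None = None,
) -> ComparisonResult:
    """Kruskal-Wallis omnibus test followed by Dunn's pairwise z tests.

    ``comparisons`` defaults to every group against the first (many-to-one,
    matching comparisons against a wild-type/control group); pass explicit
    pairs for other designs. Dunn p-values are two-sided normal tail
    probabilities, Holm-adjusted across the requested pairs.
    """
    if len(groups) < 3:
        raise ValueError("kruskal_dunn needs >= 3 groups; use mann_whitney for two")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    labels = list(arrs)
    H, p = sps.kruskal(*arrs.values())
    if comparisons is None:
        ref = labels[0]
        comparisons = [(ref, other) for other in labels[1:]]
    zs = [_dunn_z(arrs, pair) for pair in comparisons]
    raw = [float(2.0 * sps.norm.sf(abs(z))) for z in zs]
    adj = multipletests(raw, method="holm")[1] if raw else np.array([])
    return ComparisonResult(
        test="kruskal_dunn",
        statistic=float(H),
        p_value=float(p),
        comparisons=[f"{a} vs {b}" for a, b in comparisons],
        raw_p=raw,
        adjusted_p=[float(x) for x in adj],
        statistics=[float(z) for z in zs],
    )


def anova_dunnett(groups: dict[str, np.ndarray], control_label: str) -> ComparisonResult:
    """One-way ANOVA with Dunnett many-to-one comparisons vs the control.

    Zero within-group variance everywhere is degenerate and returns a
    flagged result (p = 1 when all group means coincide, else p = 0).
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    if len(groups) < 2:
        raise ValueError("anova_dunnett needs >= 2 groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    control = arrs[control_label]
    others = {k: v for k, v in arrs.items() if k != control_label}

    pooled_sse = sum(float(np.sum((v - v.mean()) ** 2)) for v in arrs.values())
    if pooled_sse == 0:
        means = [v.mean() for v in arrs.values()]
        same = np.ptp(means) == 0
        return ComparisonResult(
            test="anova_dunnett",
            statistic=0.0 if same else np.inf,
            p_value=1.0 if same else 0.0,
            comparisons=[f"{k} vs {control_label}" for k in others],
            raw_p=[1.0 if same else 0.0] * len(others),
            adjusted_p=[1.0 if same else 0.0] * len(others),
            flags=["degenerate_zero_variance"],
        )
    F, p = sps.f_oneway(*arrs.values())
    res = sps.dunnett(*others.values(), control=control)
    adj = [float(x) for x in np.atleast_1d(res.pvalue)]
    return ComparisonResult(
        test="anova_dunnett",
        statistic=float(F),
        p_value=float(p),
        comparisons=[f"{k} vs {control_label}" for k in others],
        raw_p=adj,  # Dunnett p-values are inherently familywise-adjusted
        adjusted_p=adj,
        statistics=[float(x) for x in np.atleast_1d(res.statistic)],
    )
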