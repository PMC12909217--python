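"""Gated cohort statistics: normality / variance gates, paired and
between-group tests, chi-square, Bonferroni, and -log10(p) region maps.

The decision tree mirrors common small-sample clinical practice:

* continuous data are gated by the Shapiro-Wilk test (normal iff p > 0.05);
* paired (pre/post) comparisons test the *difference scores* for normality
  and use the paired t-test when normal, otherwise the exact two-sided
  Wilcoxon signed-rank test;
* two-group comparisons use the t-test when both groups pass normality
  (Student's when Levene's variance gate passes, Welch's otherwise) and the
  exact two-sided Mann-Whitney U test otherwise;
* categorical 2x2 tables use Pearson's chi-square without continuity
  correction (Fisher's exact test available for tiny samples);
* multiplicity is handled by Bonferroni.

Test selection is a pure function of the gate outcomes and is recorded on
every result, so a rerun reproduces both the choice and the p-value.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonResult",
    "describe",
    "normality_gate",
    "variance_gate",
    "paired_compare",
    "between_compare",
    "chi_square",
    "bonferroni",
    "neglog_p_map",
]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """Outcome of one statistical comparison."""

    measure: str
    test: str
    statistic: float
    p: float
    n: tuple[int, ...]
    descriptives: dict = field(default_factory=dict)
    gates: dict = field(default_factory=dict)
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")


def describe(values) -> dict:
    """Mean +/- sample SD and median (QL, QH) descriptives.

    The SD uses the n-1 denominator; quartiles use the inclusive-median
    method (both quartile halves include the median position).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for descriptives")
    qs = statistics.quantiles(v.tolist(), n=4, method="inclusive")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
        "median": float(np.median(v)),
        "q1": float(qs[0]),
        "q3": float(qs[2]),
    }


def normality_gate(values, alpha: float = ALPHA) -> tuple[str, float, float]:
    """Shapiro-Wilk gate: ('normal'|'non-normal', W, p)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(v) == 0:
        return "non-normal", float("nan"), 0.0  # constant sample: degenerate
    w, p = stats.shapiro(v)
    return ("normal" if p > alpha else "non-normal"), float(w), float(p)


def variance_gate(g1, g2, alpha: float = ALPHA) -> tuple[str, float, float]:
    """Levene gate (centre = mean): ('homogeneous'|'heterogeneous', W, p)."""
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return "homogeneous", 0.0, 1.0  # both constant: identical spread
    w, p = stats.levene(a, b, center="mean")
    return ("homogeneous" if p > alpha else "heterogeneous"), float(w), float(p)


def paired_compare(pre, post, measure: str = "", alpha: float = ALPHA) -> ComparisonResult:
    """Pre vs post within-group comparison on difference scores.

    Differences are gated for normality; a paired t-test is used when they
    pass, otherwise the two-sided Wilcoxon signed-rank test (exact null
    distribution for n <= 25). All-zero differences yield the degenerate
    p = 1 result.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.shape != b.shape:
        raise ValueError("pre and post must have equal length")
    if a.size < 3:
        raise ValueError("paired comparison needs n >= 3")
    diff = b - a
    desc = {"pre": describe(a), "post": describe(b)}
    if np.all(diff == 0):
        return ComparisonResult(
            measure=measure, test="degenerate", statistic=0.0, p=1.0,
            n=(a.size,), descriptives=desc, degenerate=True,
        )
    gate, w, p_norm = normality_gate(diff, alpha)
    gates = {"normality": gate, "shapiro_w": w, "shapiro_p": p_norm}
    if gate == "normal":
        t, p = stats.ttest_rel(b, a)
        test, statval = "paired t", float(t)
    else:
        method = "exact" if a.size <= 25 else "auto"
        res = stats.wilcoxon(diff, method=method, alternative="two-sided")
        test, statval, p = "wilcoxon signed-rank", float(res.statistic), res.pvalue
    return ComparisonResult(
        measure=measure, test=test, statistic=statval, p=float(p),
        n=(a.size,), descriptives=desc, gates=gates,
    )


def between_compare(g1, g2, measure: str = "", alpha: float = ALPHA) -> ComparisonResult:
    """Two-group comparison with normality and variance gates.

    Both groups normal -> t-test (Student's if Levene passes, Welch's
    otherwise); any non-normal -> two-sided Mann-Whitney U (exact for small
    untied samples).
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    desc = {"g1": describe(a), "g2": describe(b)}
    if np.ptp(np.concatenate([a, b])) == 0:
        return ComparisonResult(
            measure=measure, test="degenerate", statistic=0.0, p=1.0,
            n=(a.size, b.size), descriptives=desc, degenerate=True,
        )
    gates: dict = {}
    normal = True
    for name, g in (("g1", a), ("g2", b)):
        if g.size >= 3:
            verdict, w, p_n = normality_gate(g, alpha)
        else:  # too small to test; fall through to the exact rank test
            verdict, w, p_n = "non-normal", float("nan"), float("nan")
        gates[f"normality_{name}"] = verdict
        normal &= verdict == "normal"
    if normal:
        verdict, w_l, p_l = variance_gate(a, b, alpha)
        gates["variance"] = verdict
        equal_var = verdict == "homogeneous"
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        test, statval = ("student t" if equal_var else "welch t"), float(t)
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "auto"
        res = stats.mannwhitneyu(a, b, method=method, alternative="two-sided")
        test, statval, p = "mann-whitney u", float(res.statistic), res.pvalue
    return ComparisonResult(
        measure=measure, test=test, statistic=statval, p=float(p),
        n=(a.size, b.size), descriptives=desc, gates=gates,
    )


def chi_square(table, measure: str = "", fisher: bool = False) -> ComparisonResult:
    """Pearson chi-square on a 2x2 count table (no continuity correction).

    Expected counts are reported and a warning is attached when any is
    below 5; ``fisher=True`` switches to Fisher's exact test.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal total; test undefined")
    warnings = []
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if np.any(expected < 5):
        warnings.append("expected count below 5; chi-square approximation poor")
    if fisher:
        odds, p = stats.fisher_exact(t.astype(int))
        test, statval = "fisher exact", float(odds)
    else:
        chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
        test, statval = "chi-square", float(chi2)
    return ComparisonResult(
        measure=measure, test=test, statistic=statval, p=float(p),
        n=(int(t[0].sum()), int(t[1].sum())),
        descriptives={"expected": expected.tolist()},
        warnings=warnings,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` with m the family size."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def neglog_p_map(
    per_region_pre: dict[str, np.ndarray],
    per_region_post: dict[str, np.ndarray],
    alpha: float = ALPHA,
) -> dict[str, dict]:
    """Region-wise paired comparison rendered as -log10(p) map values.

    Returns ``region -> {neglog_p, p, test, significant}``; the significance
    flag uses the configured level on the raw p-value.
    """
    if set(per_region_pre) != set(per_region_post):
        raise ValueError("pre and post must cover the same regions")
    out = {}
    for region in per_region_pre:
        res = paired_compare(per_region_pre[region], per_region_post[region],
                             measure=region, alpha=alpha)
        out[region] = {
            "neglog_p": float(-np.log10(max(res.p, 1e-300))),
            "p": res.p,
            "test": res.test,
            "significant": res.p < alpha,
        }
    return out
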