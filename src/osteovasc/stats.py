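"""Group-comparison statistics for cohort morphometry tables.

The testing scheme mirrors standard practice in small-animal µCT studies:
each group is first checked for normality with the Lilliefors test (a
Kolmogorov–Smirnov-type test with mean and variance estimated from the
sample, p-value obtained by Monte Carlo), variance homogeneity across groups
is checked with Bartlett's test, and group differences are then assessed with
the one-way ANOVA F-test.  Significance is flagged at the three conventional
tiers p < 0.05, p < 0.01, p < 0.001.  No multiple-testing correction is
applied by default; a Bonferroni flag is available.

When assumption checks fail the ANOVA result is still computed but carries an
``assumptions_met=False`` flag and no significance tier (unless explicitly
overridden); no nonparametric fallback is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "significance_tier",
    "lilliefors_test",
    "variance_homogeneity",
    "anova_f",
    "run_study_comparisons",
    "results_frame",
    "GLOBAL_METRICS",
    "LOCAL_METRICS",
]

DEFAULT_TIERS = (0.05, 0.01, 0.001)
GLOBAL_METRICS = ("BV/TV", "VV/TV", "V.Th", "MeV/TV")
LOCAL_METRICS = ("local VV/TV", "local V.Th")


@dataclass
class TestResult:
    """Outcome of one hypothesis test with its assumption checks."""

    name: str
    statistic: float
    p_value: float
    df: tuple | None = None
    tier: float | None = None  # smallest alpha tier the p-value clears, or None
    assumptions_met: bool | None = None
    assumption_results: list["TestResult"] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    metric: str | None = None
    groups: tuple | None = None

    def as_dict(self) -> dict:
        return {
            "test": self.name,
            "metric": self.metric,
            "groups": "|".join(map(str, self.groups)) if self.groups else None,
            "statistic": self.statistic,
            "df": "|".join(map(str, self.df)) if self.df else None,
            "p_value": self.p_value,
            "tier": self.tier,
            "assumptions_met": self.assumptions_met,
            "warnings": "; ".join(self.warnings) or None,
        }


def significance_tier(p: float, tiers=DEFAULT_TIERS) -> float | None:
    """Smallest alpha in ``tiers`` with p < alpha (the conventional star level),
    or ``None`` when no tier is cleared."""
    cleared = [a for a in tiers if p < a]
    return min(cleared) if cleared else None


# ---------------------------------------------------------------------------
# Lilliefors


def _lilliefors_statistic(samples: np.ndarray) -> np.ndarray:
    """Sup-distance between the EDF and the normal CDF with sample-estimated
    mean and SD, vectorized over the rows of a 2D array."""
    samples = np.atleast_2d(samples)
    n = samples.shape[1]
    xs = np.sort(samples, axis=1)
    mean = xs.mean(axis=1, keepdims=True)
    sd = xs.std(axis=1, ddof=1, keepdims=True)
    z = (xs - mean) / sd
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors_test(sample, n_montecarlo: int = 2000, seed: int = 0) -> TestResult:
    """Lilliefors normality test with a Monte-Carlo p-value.

    The null distribution of the statistic is simulated by drawing
    ``n_montecarlo`` standard-normal samples of the same size and applying the
    same estimate-then-compare step; the p-value uses the add-one rule
    p = (1 + #{D* >= D}) / (1 + n_montecarlo).  Deterministic given ``seed``.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("Lilliefors test needs a 1D sample with n >= 4")
    if n_montecarlo < 1000:
        raise ValueError("n_montecarlo must be >= 1000 for a stable p-value")
    if np.std(x, ddof=1) == 0:
        raise ValueError("constant sample: normality test undefined")
    d_obs = float(_lilliefors_statistic(x[None, :])[0])
    rng = np.random.default_rng(seed)
    null = _lilliefors_statistic(rng.standard_normal((n_montecarlo, x.size)))
    p = (1.0 + np.count_nonzero(null >= d_obs)) / (1.0 + n_montecarlo)
    return TestResult(name="lilliefors", statistic=d_obs, p_value=float(p), df=(x.size,))


# ---------------------------------------------------------------------------
# Bartlett and ANOVA


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.ndim != 1 or g.size < 2:
            raise ValueError("each group needs at least two observations")
    return gs


def variance_homogeneity(groups) -> TestResult:
    """Bartlett's test of equal variances (chi-square p-value)."""
    gs = _check_groups(groups)
    if any(np.var(g, ddof=1) == 0 for g in gs):
        raise ValueError("zero-variance group: Bartlett's test undefined")
    stat, p = sps.bartlett(*gs)
    return TestResult(name="bartlett", statistic=float(stat), p_value=float(p), df=(len(gs) - 1,))


def anova_f(groups, tiers=DEFAULT_TIERS) -> TestResult:
    """One-way ANOVA F-test.

    F = (between-group SS / (k−1)) / (within-group SS / (N−k)); for two groups
    this equals the square of the pooled-variance t statistic.  Zero
    within-group SS with nonzero between-group SS yields p = 0 with a
    degenerate-data warning.
    """
    gs = _check_groups(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    if n_total <= k:
        raise ValueError("total sample size must exceed the number of groups")
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df = (k - 1, n_total - k)
    warnings = []
    if ssw == 0:
        if ssb == 0:
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
            warnings.append("degenerate data: zero within-group variance")
    else:
        f = (ssb / df[0]) / (ssw / df[1])
        p = float(sps.f.sf(f, *df))
    res = TestResult(name="anova_f", statistic=float(f), p_value=float(p), df=df, warnings=warnings)
    res.tier = significance_tier(res.p_value, tiers) if tiers else None
    return res


# ---------------------------------------------------------------------------
# study-design comparisons


def _one_comparison(
    metric: str,
    group_values: dict[str, np.ndarray],
    tiers,
    n_montecarlo: int,
    seed: int,
    assumption_override: bool,
    bonferroni: int = 1,
) -> TestResult:
    checks: list[TestResult] = []
    ok = True
    for i, (label, vals) in enumerate(sorted(group_values.items())):
        try:
            lt = lilliefors_test(vals, n_montecarlo=n_montecarlo, seed=seed + 17 * i)
        except ValueError as exc:
            lt = TestResult(name="lilliefors", statistic=np.nan, p_value=np.nan, warnings=[str(exc)])
        lt.metric = metric
        lt.groups = (label,)
        checks.append(lt)
        if not (lt.p_value >= 0.05):  # rejection or undefined
            ok = False
    try:
        bart = variance_homogeneity(list(group_values.values()))
    except ValueError as exc:
        bart = TestResult(name="bartlett", statistic=np.nan, p_value=np.nan, warnings=[str(exc)])
    bart.metric = metric
    bart.groups = tuple(sorted(group_values))
    checks.append(bart)
    if not (bart.p_value >= 0.05):
        ok = False
    res = anova_f(list(group_values.values()), tiers=None)
    if bonferroni > 1:
        res.p_value = min(1.0, res.p_value * bonferroni)
        res.warnings.append(f"Bonferroni-corrected over {bonferroni} comparisons")
    res.metric = metric
    res.groups = tuple(sorted(group_values))
    res.assumptions_met = ok
    res.assumption_results = checks
    if tiers and (ok or assumption_override):
        res.tier = significance_tier(res.p_value, tiers)
        if not ok:
            res.warnings.append("tier attached despite failed assumption checks (override)")
    return res


def run_study_comparisons(
    table: pd.DataFrame,
    tiers=DEFAULT_TIERS,
    n_montecarlo: int = 2000,
    seed: int = 0,
    assumption_override: bool = False,
    bonferroni: bool = False,
) -> list[TestResult]:
    """Run the study's comparison design on a cohort table.

    The table is long-form with columns ``sample_id, time_point, group,
    metric, value``.  Comparisons: (a) T1 vs T2 for the global metrics BV/TV,
    VV/TV, V.Th, MeV/TV; (b) the T2 treatment groups against each other for
    the VOI-restricted metrics (local VV/TV, local V.Th).  Each ANOVA is
    preceded by per-group Lilliefors and Bartlett checks whose outcomes are
    attached to the result.  No multiple-testing correction unless
    ``bonferroni=True``.
    """
    required = {"sample_id", "time_point", "group", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"cohort table misses columns {sorted(required - set(table.columns))}")
    results: list[TestResult] = []
    time_points = set(table["time_point"])
    jobs: list[tuple[str, dict[str, np.ndarray]]] = []
    if {"T1", "T2"}.issubset(time_points):
        for metric in GLOBAL_METRICS:
            sub = table[table["metric"] == metric]
            if sub.empty:
                raise ValueError(f"cohort table has no values for metric {metric!r}")
            jobs.append(
                (metric, {tp: sub[sub["time_point"] == tp]["value"].to_numpy() for tp in ("T1", "T2")})
            )
    t2 = table[table["time_point"] == "T2"]
    t2_groups = sorted(set(t2["group"]))
    if len(t2_groups) >= 2:
        for metric in LOCAL_METRICS:
            sub = t2[t2["metric"] == metric].dropna(subset=["value"])
            if sub.empty:
                raise ValueError(f"cohort table has no T2 values for metric {metric!r}")
            groups = {g: sub[sub["group"] == g]["value"].to_numpy() for g in t2_groups}
            groups = {g: v for g, v in groups.items() if v.size >= 2}
            if len(groups) < 2:
                raise ValueError(f"metric {metric!r}: fewer than two T2 groups with n >= 2")
            jobs.append((metric, groups))
    if not jobs:
        raise ValueError("table contains neither a T1/T2 contrast nor >= 2 T2 groups")
    m = len(jobs) if bonferroni else 1
    for i, (metric, groups) in enumerate(jobs):
        results.append(
            _one_comparison(
                metric, groups, tiers, n_montecarlo, seed + 1000 * i, assumption_override, m
            )
        )
    return results


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    """Flatten test results (with their assumption checks) into a table."""
    rows = []
    for r in results:
        rows.append(r.as_dict())
        rows.extend(chk.as_dict() for chk in r.assumption_results)
    return pd.DataFrame(rows)
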