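"""Statistical evaluation of coupon-level coverage between groups.

The workflow mirrors standard materials-testing practice: each group of
per-coupon pooled coverages is first screened with a battery of four
normality tests (Shapiro-Wilk, Kolmogorov-Smirnov, Lilliefors,
Anderson-Darling); trials of one material are compared with one-way
ANOVA plus Tukey's range test for pairwise post-hoc contrasts; two
materials are compared with a two-sample t-test (Welch by default).
The default significance level is 5%; because material-discrimination
claims are often also reported at the 0.1% level, decisions are printed
at both.

Notes on the battery: the Kolmogorov-Smirnov entry uses the classical
KS null distribution with mean and sd estimated from the sample — the
textbook (anti-conservative) variant — while the Lilliefors entry uses
the same D statistic with a null calibrated for estimated parameters,
either via the statsmodels table or by seeded Monte-Carlo simulation.
The Anderson-Darling p-value uses the Stephens small-sample correction
and the standard piecewise exponential approximation for the
estimated-parameter case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

from .errors import DataError, ValidationError

DEFAULT_ALPHA = 0.05
REPORT_ALPHAS = (0.05, 0.001)
NORMALITY_TESTS = ("shapiro_wilk", "kolmogorov_smirnov", "lilliefors", "anderson_darling")


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float

    def rejects(self, alpha: float) -> bool:
        return self.p_value < alpha


@dataclass
class NormalityReport:
    tests: dict[str, TestResult]
    alpha: float
    normal: bool  # joint verdict: no test rejects at alpha


def _check_sample(x: np.ndarray, min_n: int, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError(f"{what}: expected a 1-D sample")
    if not np.isfinite(x).all():
        raise ValidationError(f"{what}: sample contains non-finite values")
    if x.size < min_n:
        raise DataError(f"{what}: need at least {min_n} observations, got {x.size}")
    return x


def anderson_darling_normal(x: np.ndarray) -> TestResult:
    """Anderson-Darling test for normality with estimated parameters.

    Applies the Stephens small-sample correction
    A*^2 = A^2 (1 + 0.75/n + 2.25/n^2) and the piecewise exponential
    p-value approximation for the composite-normal case.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    eps = 1e-12
    cdf = np.clip(cdf, eps, 1 - eps)
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1]))) / n
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2s >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s**2)
    elif a2s > 0.34:
        p = np.exp(0.9177 - 4.279 * a2s - 1.38 * a2s**2)
    elif a2s > 0.2:
        p = 1 - np.exp(-8.318 + 42.796 * a2s - 59.938 * a2s**2)
    else:
        p = 1 - np.exp(-13.436 + 101.14 * a2s - 223.73 * a2s**2)
    return TestResult("anderson_darling", float(a2s), float(np.clip(p, 0.0, 1.0)))


def _ks_statistic_estimated(x: np.ndarray) -> float:
    z = (x - x.mean()) / x.std(ddof=1)
    return float(stats.kstest(z, "norm").statistic)


def lilliefors_mc(x: np.ndarray, n_mc: int = 2000, seed: int = 0) -> TestResult:
    """Lilliefors test with a seeded Monte-Carlo null distribution.

    The D statistic is the KS distance of the standardized sample from
    N(0,1); its null is simulated by drawing ``n_mc`` standard-normal
    samples of the same size and recomputing D with estimated
    parameters each time (add-one empirical p-value).
    """
    x = np.asarray(x, dtype=float)
    d_obs = _ks_statistic_estimated(x)
    rng = np.random.default_rng(seed)
    n = x.size
    hits = 0
    for _ in range(n_mc):
        sim = rng.standard_normal(n)
        if _ks_statistic_estimated(sim) >= d_obs:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    return TestResult("lilliefors", d_obs, float(p))


def normality_battery(
    sample: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    lilliefors_method: str = "table",
    n_mc: int = 2000,
    seed: int = 0,
) -> NormalityReport:
    """Run the four-test normality battery on one group.

    The joint verdict is "normal" iff none of the four tests rejects at
    ``alpha`` — a deliberately strict gate, since each test is sensitive
    to a different departure. ``lilliefors_method`` is ``"table"``
    (statsmodels lookup) or ``"mc"`` (in-repo seeded Monte-Carlo).
    """
    x = _check_sample(np.asarray(sample), 3, "normality battery")
    if x.std(ddof=1) == 0:
        raise DataError("normality battery: sample has zero variance")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")

    sw_stat, sw_p = stats.shapiro(x)
    z = (x - x.mean()) / x.std(ddof=1)
    ks = stats.kstest(z, "norm")
    if lilliefors_method == "table":
        lf_stat, lf_p = sm_lilliefors(x, dist="norm")
        lf = TestResult("lilliefors", float(lf_stat), float(lf_p))
    elif lilliefors_method == "mc":
        lf = lilliefors_mc(x, n_mc=n_mc, seed=seed)
    else:
        raise ValidationError(f"unknown lilliefors_method {lilliefors_method!r}")
    tests = {
        "shapiro_wilk": TestResult("shapiro_wilk", float(sw_stat), float(sw_p)),
        "kolmogorov_smirnov": TestResult("kolmogorov_smirnov", float(ks.statistic), float(ks.pvalue)),
        "lilliefors": lf,
        "anderson_darling": anderson_darling_normal(x),
    }
    normal = not any(t.rejects(alpha) for t in tests.values())
    return NormalityReport(tests=tests, alpha=alpha, normal=normal)


# ---------------------------------------------------------------------------
# multi-group comparison

@dataclass
class TrialComparison:
    groups: dict[str, np.ndarray]
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    tukey: pd.DataFrame          # pair, mean_diff, ci_low, ci_high, p_adj
    max_mean_diff: float
    normality: dict[str, NormalityReport]
    alpha: float

    def decisions(self, alphas: Sequence[float] = REPORT_ALPHAS) -> dict[float, bool]:
        """ANOVA rejection decision at each reporting level."""
        return {a: self.anova_p < a for a in alphas}


def compare_trials(
    groups: Mapping[str, Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
    check_normality: bool = True,
    post_hoc: bool = True,
) -> TrialComparison:
    """One-way ANOVA with Tukey HSD across k >= 3 named groups.

    Groups that fail the normality battery are flagged in the report but
    still enter the ANOVA (the gate informs interpretation, it does not
    silently drop data). Also reports the maximum pairwise difference of
    group means — the practically relevant effect size when no contrast
    is significant. ``post_hoc=False`` skips the Tukey table (useful in
    simulation loops that only consume the ANOVA decision).
    """
    if len(groups) < 3:
        raise ValidationError("compare_trials needs at least 3 groups (use compare_materials for 2)")
    arrays = {}
    for name, values in groups.items():
        arr = _check_sample(np.asarray(values), 2, f"group {name!r}")
        arrays[name] = arr
    normality = {}
    if check_normality:
        for name, arr in arrays.items():
            if arr.size >= 3 and arr.std(ddof=1) > 0:
                normality[name] = normality_battery(arr, alpha=alpha)
    samples = list(arrays.values())
    f, p = stats.f_oneway(*samples)
    k = len(samples)
    n_total = sum(a.size for a in samples)
    if np.isnan(f):  # all groups constant and equal
        f, p = 0.0, 1.0
    names = list(arrays.keys())
    rows = []
    if post_hoc:
        res = stats.tukey_hsd(*samples)
        ci = res.confidence_interval(confidence_level=1 - alpha)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "mean_diff": float(arrays[names[i]].mean() - arrays[names[j]].mean()),
                        "ci_low": float(ci.low[i, j]),
                        "ci_high": float(ci.high[i, j]),
                        "p_adj": float(res.pvalue[i, j]),
                    }
                )
    tukey = pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_diff", "ci_low", "ci_high", "p_adj"]
    )
    means = np.array([a.mean() for a in samples])
    return TrialComparison(
        groups=arrays,
        anova_f=float(f),
        anova_df=(k - 1, n_total - k),
        anova_p=float(p),
        tukey=tukey,
        max_mean_diff=float(means.max() - means.min()),
        normality=normality,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# two-group comparison

@dataclass
class MaterialComparison:
    statistic: float
    df: float
    p_value: float
    mean_diff: float
    ci_low: float
    ci_high: float
    mean_ratio: float
    alpha: float
    equal_var: bool

    def decisions(self, alphas: Sequence[float] = REPORT_ALPHAS) -> dict[float, bool]:
        return {a: self.p_value < a for a in alphas}


def compare_materials(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = False,
) -> MaterialComparison:
    """Two-sample t-test between two materials' coverage samples.

    Welch's unequal-variance form by default (``equal_var=True`` for the
    pooled Student form). Reports the two-sided p, the mean difference
    with its (1 - alpha) confidence interval, and the ratio of means —
    the "coverage doubled on material B" style effect measure. Two
    identical constant samples are a documented degenerate path with
    p = 1 and zero difference.
    """
    a = _check_sample(np.asarray(group_a), 2, "group A")
    b = _check_sample(np.asarray(group_b), 2, "group B")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # t undefined; equal means -> no evidence of difference, else infinite t
        diff = a.mean() - b.mean()
        p = 1.0 if diff == 0 else 0.0
        return MaterialComparison(
            statistic=0.0 if diff == 0 else np.inf * np.sign(diff),
            df=float(a.size + b.size - 2),
            p_value=p,
            mean_diff=float(diff),
            ci_low=float(diff),
            ci_high=float(diff),
            mean_ratio=float(a.mean() / b.mean()) if b.mean() != 0 else np.nan,
            alpha=alpha,
            equal_var=equal_var,
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return MaterialComparison(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_diff=float(a.mean() - b.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        mean_ratio=float(a.mean() / b.mean()) if b.mean() != 0 else np.nan,
        alpha=alpha,
        equal_var=equal_var,
    )


# ---------------------------------------------------------------------------
# report assembly

def full_report(
    groups: Mapping[str, Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
    lilliefors_method: str = "table",
    seed: int = 0,
) -> dict:
    """Orchestrate the evaluation for a set of named coverage groups.

    Normality battery per group; one-way ANOVA + Tukey when 3 or more
    groups are given; Welch t-test for every pair when exactly 2 are.
    Returns a plain dict ready for JSON/CSV serialization, with
    decisions reported at the 5% and 0.1% levels.
    """
    names = list(groups.keys())
    out: dict = {"alpha": alpha, "groups": {}}
    for name in names:
        x = np.asarray(groups[name], dtype=float)
        entry = {
            "n": int(x.size),
            "mean_pct": float(x.mean()),
            "sd_pct": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        }
        if x.size >= 3 and x.std(ddof=1) > 0:
            rep = normality_battery(x, alpha=alpha, lilliefors_method=lilliefors_method, seed=seed)
            entry["normality"] = {
                name_: {"statistic": t.statistic, "p_value": t.p_value}
                for name_, t in rep.tests.items()
            }
            entry["normal"] = rep.normal
        out["groups"][name] = entry
    if len(names) >= 3:
        cmp_ = compare_trials(groups, alpha=alpha)
        out["anova"] = {
            "F": cmp_.anova_f,
            "df": list(cmp_.anova_df),
            "p_value": cmp_.anova_p,
            "max_mean_diff_pct": cmp_.max_mean_diff,
            "decisions": {str(a): bool(d) for a, d in cmp_.decisions().items()},
        }
        out["tukey"] = cmp_.tukey.to_dict(orient="records")
    elif len(names) == 2:
        mc = compare_materials(groups[names[0]], groups[names[1]], alpha=alpha)
        out["t_test"] = {
            "comparison": f"{names[0]} vs {names[1]}",
            "statistic": mc.statistic,
            "df": mc.df,
            "p_value": mc.p_value,
            "mean_diff_pct": mc.mean_diff,
            "ci": [mc.ci_low, mc.ci_high],
            "mean_ratio": mc.mean_ratio,
            "decisions": {str(a): bool(d) for a, d in mc.decisions().items()},
        }
    return out


def save_boxplot(groups: Mapping[str, Sequence[float]], png_path) -> None:
    """Box-whisker plot of coverage per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    ax.boxplot([np.asarray(v, dtype=float) for v in groups.values()],
               tick_labels=list(groups.keys()))
    ax.set_ylabel("surface coverage (%)")
    path = Path(png_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
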