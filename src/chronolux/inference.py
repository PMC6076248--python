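"""Group-level inference for psychometric parameters.

The analysis layer mirrors common psychophysics practice for small
within-subject designs (n = 8): screen each condition's parameter values
with the Shapiro-Wilk test; compare two conditions with a classical paired t
when normality holds, or with a nonparametric bootstrap of the paired
differences when it does not; compare three conditions with a one-way
repeated-measures ANOVA (uncorrected univariate F, partial eta squared) and
Bonferroni-corrected pairwise paired t tests; and compare effect estimates
across independent experiments with a Welch t built from group summaries.

Both the parametric and the bootstrap route are always computed and logged;
the normality screen only selects which one a report headlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSamples",
    "BootTestResult",
    "PairwiseResult",
    "RmAnovaResult",
    "WelchResult",
    "shapiro_wilk",
    "bootstrap_paired_test",
    "paired_t_test",
    "rm_anova_oneway",
    "bonferroni_pairwise",
    "welch_t_from_summaries",
]


@dataclass(frozen=True)
class PairedSamples:
    """Per-participant values under two conditions, aligned by participant."""

    first: np.ndarray
    second: np.ndarray
    labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        a = np.asarray(self.first, dtype=float)
        b = np.asarray(self.second, dtype=float)
        if a.ndim != 1 or a.shape != b.shape:
            raise ValueError("paired samples must be aligned 1-D arrays")
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise ValueError("paired samples must not contain missing values")
        object.__setattr__(self, "first", a)
        object.__setattr__(self, "second", b)

    @property
    def differences(self) -> np.ndarray:
        return self.first - self.second

    def __len__(self) -> int:
        return len(self.first)


@dataclass(frozen=True)
class BootTestResult:
    observed_mean_diff: float
    bootstrapped_mean: float
    ci95: tuple[float, float]
    p_value: float
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.bootstrapped_mean <= hi):
            raise ValueError("bootstrap mean must lie inside its own CI")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must be in (0, 1]")


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    mean_diff: float
    t: float
    df: int
    p_uncorrected: float
    p_corrected: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class RmAnovaResult:
    F: float
    df_effect: int
    df_error: int
    p_value: float
    partial_eta_sq: float
    ss_conditions: float
    ss_subjects: float
    ss_error: float
    pairwise: tuple[PairwiseResult, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be >= 0")
        if not 0.0 <= self.partial_eta_sq <= 1.0:
            raise ValueError("partial eta squared must lie in [0, 1]")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float
    ci95: tuple[float, float]


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's approximation), for 3 <= n <= 50."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not (3 <= len(x) <= 50):
        raise ValueError("Shapiro-Wilk supported for 1-D samples with 3 <= n <= 50")
    if np.ptp(x) == 0.0:
        raise ValueError("Shapiro-Wilk undefined for a zero-variance sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def bootstrap_paired_test(
    pairs: PairedSamples, n_iter: int = 100_000, seed: int = 0
) -> BootTestResult:
    """Nonparametric bootstrap of the mean paired difference.

    Difference scores are resampled with replacement ``n_iter`` times.  The
    95% CI is the percentile interval of the resampled means.  The two-sided
    p-value is the equal-tailed studentized (bootstrap-t) p: each centered
    resample contributes a t statistic, and p = 2 * min(tail fractions) of
    the observed t within that null distribution, with a +1 continuity
    correction so p is never exactly zero.  The studentized form keeps the
    test close to its nominal size even at n = 8, where a plain mean-based
    shifted-null p is markedly anticonservative.
    """
    if len(pairs) < 4:
        raise ValueError("bootstrap paired test needs >= 4 pairs")
    d = pairs.differences
    if np.ptp(d) == 0.0 and d[0] == 0.0:
        # all differences identically zero: no effect, maximally null
        return BootTestResult(0.0, 0.0, (0.0, 0.0), 1.0, n_iter, seed)
    if np.ptp(d) == 0.0:
        raise ValueError("zero-variance nonzero differences; bootstrap degenerate")
    rng = np.random.default_rng(seed)
    observed = float(np.mean(d))
    n = len(d)
    idx = rng.integers(0, n, size=(n_iter, n))
    samples = d[idx]
    boot_means = samples.mean(axis=1)
    ci = (float(np.percentile(boot_means, 2.5)), float(np.percentile(boot_means, 97.5)))
    t_obs = observed / (np.std(d, ddof=1) / np.sqrt(n))
    null_means = boot_means - observed  # centered: the null resampling law
    null_se = samples.std(ddof=1, axis=1) / np.sqrt(n)
    ok = null_se > 0.0  # degenerate (all-identical) resamples carry no t
    t_null = null_means[ok] / null_se[ok]
    n_ok = int(np.sum(ok))
    lo_tail = (1.0 + np.sum(t_null <= t_obs)) / (n_ok + 1.0)
    hi_tail = (1.0 + np.sum(t_null >= t_obs)) / (n_ok + 1.0)
    p = min(1.0, 2.0 * min(lo_tail, hi_tail))
    return BootTestResult(
        observed_mean_diff=observed,
        bootstrapped_mean=float(np.mean(boot_means)),
        ci95=ci,
        p_value=float(p),
        n_iterations=n_iter,
        seed=seed,
    )


def paired_t_test(pairs: PairedSamples) -> tuple[float, int, float, tuple[float, float]]:
    """Classical paired t on the difference scores: (t, df, p, 95% CI)."""
    if len(pairs) < 3:
        raise ValueError("paired t test needs >= 3 pairs")
    d = pairs.differences
    n = len(d)
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if np.all(d == 0.0):
            return 0.0, n - 1, 1.0, (0.0, 0.0)
        raise ValueError("zero-variance differences")
    se = sd / np.sqrt(n)
    t = float(np.mean(d) / se)
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    mean = float(np.mean(d))
    return t, df, p, (mean - tcrit * se, mean + tcrit * se)


def _as_table(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), [str(c) for c in table.columns]
    arr = np.asarray(table, dtype=float)
    return arr, [f"C{j + 1}" for j in range(arr.shape[1])]


def rm_anova_oneway(table) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a participants x conditions table.

    Univariate within-subject decomposition with no sphericity correction:
    SS_total = SS_conditions + SS_subjects + SS_error, F = MS_cond / MS_error
    with df (c-1, (c-1)(s-1)), and partial eta^2 = SS_cond/(SS_cond+SS_error).
    """
    x, labels = _as_table(table)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete table with >= 2 participants and >= 2 conditions")
    if np.any(~np.isfinite(x)):
        raise ValueError("incomplete table: missing values are not supported")
    s, c = x.shape
    grand = x.mean()
    ss_cond = s * float(np.sum((x.mean(axis=0) - grand) ** 2))
    ss_subj = c * float(np.sum((x.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_eff = c - 1
    df_err = (c - 1) * (s - 1)
    ms_cond = ss_cond / df_eff
    ms_err = ss_err / df_err
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ss_cond == 0.0 else np.inf)
    p = float(stats.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
    eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return RmAnovaResult(
        F=float(F),
        df_effect=df_eff,
        df_error=df_err,
        p_value=p,
        partial_eta_sq=float(eta),
        ss_conditions=ss_cond,
        ss_subjects=ss_subj,
        ss_error=ss_err,
        pairwise=bonferroni_pairwise(table),
    )


def bonferroni_pairwise(table) -> tuple[PairwiseResult, ...]:
    """Paired t per condition pair with Bonferroni-corrected p-values.

    Corrected p is the raw p multiplied by the number of pairs, capped at 1;
    the 95% CI of each mean difference is uncorrected.
    """
    x, labels = _as_table(table)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 conditions")
    pairs = list(combinations(range(x.shape[1]), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        d = x[:, i] - x[:, j]
        if np.ptp(d) == 0.0 and d[0] != 0.0:
            # constant nonzero difference: the effect is exact, not estimable
            # by a t statistic; report it as maximally significant
            t, df, p = np.inf * np.sign(d[0]), x.shape[0] - 1, 0.0
            ci = (float(d[0]), float(d[0]))
        else:
            t, df, p, ci = paired_t_test(
                PairedSamples(x[:, i], x[:, j], labels=(labels[i], labels[j]))
            )
        out.append(
            PairwiseResult(
                pair=(labels[i], labels[j]),
                mean_diff=float(np.mean(x[:, i] - x[:, j])),
                t=t,
                df=df,
                p_uncorrected=p,
                p_corrected=min(1.0, m * p),
                ci95=ci,
            )
        )
    return tuple(out)


def welch_t_from_summaries(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> WelchResult:
    """Welch two-sample t from group means and standard errors.

    Satterthwaite degrees of freedom; the CI is on mean1 - mean2.  With equal
    n and equal SE the df reduce to 2(n - 1) exactly.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = se1**2, se2**2
    diff = mean1 - mean2
    se = np.sqrt(v1 + v2)
    t = diff / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return WelchResult(
        t=float(t), df=float(df), p_value=p, ci95=(diff - tcrit * se, diff + tcrit * se)
    )
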