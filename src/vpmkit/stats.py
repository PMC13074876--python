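"""Blind-zone statistics: paired Wilcoxon tests, Bonferroni control, effect
sizes, two-proportion z-tests and binomial confidence intervals.

Per-level completeness scores from two detector configurations are compared
frame-by-frame with a paired Wilcoxon signed-rank test at each of the 17
vertebral levels; the family-wise error rate over the 17 tests is controlled
with Bonferroni at alpha = 0.05 / 17.  Effect size is r = |Z| / sqrt(N) with
N the number of paired frame samples.  Pooled-count contrasts (one level
against the rest) use a pooled two-proportion z-test without continuity
correction, and per-level accuracies carry Wilson score intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .core import LEVELS, N_LEVELS, VertebralLevel, level_from_name

__all__ = [
    "FAMILY_ALPHA",
    "N_TESTS",
    "DegenerateTestError",
    "PairedLevelSamples",
    "TestResult",
    "wilcoxon_signed_rank",
    "effect_size_r",
    "bonferroni",
    "two_proportion_ztest",
    "binomial_ci",
    "run_paired_tests",
]

#: Family-wise significance level and family size (the 17 vertebral levels).
FAMILY_ALPHA = 0.05
N_TESTS = N_LEVELS

#: Exact null enumeration is used up to this many nonzero differences.
EXACT_LIMIT = 25


class DegenerateTestError(ValueError):
    """The test statistic is undefined on this input (no usable signal)."""


@dataclass(frozen=True)
class PairedLevelSamples:
    """Per-frame completeness scores for one level under two configurations.

    ``a`` and ``b`` are paired by frame (same frame, two detector
    configurations); values are indicators or scores in [0, 1].
    """

    level: VertebralLevel
    a: tuple[float, ...]
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("paired samples must have equal length")
        for v in (*self.a, *self.b):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"scores must lie in [0, 1], got {v}")

    @property
    def n_pairs(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class TestResult:
    """Wilcoxon outcome for one level, with family-wise adjustment built in."""

    level: Optional[VertebralLevel]
    statistic: float  # W+ (sum of positive-difference ranks)
    z_value: float
    p_value: float
    p_adjusted: float
    effect_size_r: float
    n_pairs: int
    n_nonzero: int
    method: str  # "exact" or "normal-approx"
    significant: bool  # raw p < FAMILY_ALPHA / N_TESTS


def _signed_rank_parts(diffs: np.ndarray):
    nz = diffs[diffs != 0.0]
    if nz.size == 0:
        raise DegenerateTestError(
            "all paired differences are zero: the signed-rank statistic is "
            "undefined (no evidence either way)"
        )
    ranks = sps.rankdata(np.abs(nz))  # average ranks for ties
    w_plus = float(ranks[nz > 0].sum())
    return nz, ranks, w_plus


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating the 2^m equiprobable sign patterns.

    Tied absolute differences get average ranks, so ranks are multiples of
    1/2; scaling by 2 makes them integers and the null distribution of
    2*W+ is computed by a shift-DP (subset-sum convolution).
    """
    scaled = np.rint(2.0 * ranks).astype(int)
    total = int(scaled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in scaled:
        counts[r:] += counts[:-r].copy() if r else counts.copy()
    n_patterns = counts.sum()
    target = int(round(2.0 * w_plus))
    lower = counts[: target + 1].sum() / n_patterns
    upper = counts[target:].sum() / n_patterns
    return float(min(1.0, 2.0 * min(lower, upper)))


def _approx_z(nz: np.ndarray, ranks: np.ndarray, w_plus: float) -> float:
    m = nz.size
    mu = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    # tie correction on the absolute differences
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise DegenerateTestError("zero variance after tie correction")
    return float((w_plus - mu) / sqrt(var))


def wilcoxon_signed_rank(samples: PairedLevelSamples) -> TestResult:
    """Paired Wilcoxon signed-rank test between two configurations.

    Zero differences are discarded; absolute differences are ranked with
    average ranks for ties.  The two-sided p-value is exact (sign-pattern
    enumeration via a subset-sum DP) up to 25 nonzero pairs and a
    tie-corrected normal approximation beyond that.  The normalised Z is
    always reported so the effect size r = |Z|/sqrt(N) is available.
    """
    diffs = np.asarray(samples.a, dtype=float) - np.asarray(samples.b, dtype=float)
    nz, ranks, w_plus = _signed_rank_parts(diffs)
    z = _approx_z(nz, ranks, w_plus)
    if nz.size <= EXACT_LIMIT:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "exact"
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal-approx"
    r = effect_size_r(z, samples.n_pairs)
    return TestResult(
        level=samples.level,
        statistic=w_plus,
        z_value=z,
        p_value=p,
        p_adjusted=min(1.0, N_TESTS * p),
        effect_size_r=r,
        n_pairs=samples.n_pairs,
        n_nonzero=int(nz.size),
        method=method,
        significant=p < FAMILY_ALPHA / N_TESTS,
    )


def effect_size_r(z_value: float, n_pairs: int) -> float:
    """Wilcoxon effect size r = |Z| / sqrt(N) for N paired samples."""
    if n_pairs < 1:
        raise ValueError("effect size requires at least one pair")
    return abs(z_value) / sqrt(n_pairs)


def bonferroni(p_values: Sequence[float]) -> list[tuple[float, bool]]:
    """Bonferroni adjustment over the 17-level family.

    Returns ``(adjusted_p, significant)`` per level, where adjusted_p =
    min(1, 17 * p) and significance is raw p < 0.05/17.  The family is the
    17 vertebral levels, so exactly 17 p-values are required.
    """
    if len(p_values) != N_TESTS:
        raise ValueError(f"expected {N_TESTS} p-values (one per level), got {len(p_values)}")
    out = []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {p}")
        out.append((min(1.0, N_TESTS * p), p < FAMILY_ALPHA / N_TESTS))
    return out


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided, no continuity correction.

    Returns ``(z, p)``.  ``z`` is positive when the first proportion is
    larger.  Degenerate when the pooled proportion is 0 or 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not (0 <= k <= n):
            raise ValueError(f"invalid counts: k={k}, n={n}")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateTestError("pooled proportion is degenerate (0 or 1)")
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def binomial_ci(
    k: int, n: int, confidence: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Binomial confidence interval for k successes in n trials.

    Wilson score interval by default; any method supported by
    ``statsmodels.stats.proportion.proportion_confint`` may be named.
    """
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"invalid counts: k={k}, n={n}")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    low, high = proportion_confint(k, n, alpha=1.0 - confidence, method=method)
    return float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0))


def run_paired_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Per-level Wilcoxon tests from a paired long-format table.

    ``table`` must have columns ``frame_id``, ``level``, ``config_a``,
    ``config_b`` with one row per (frame, level) pair; every level must be
    present.  Returns a 17-row table (level, n_pairs, statistic, z, p,
    p_adjusted, r, significant, method), with degenerate levels reported as
    no-evidence rows (NaN statistics, not significant).
    """
    required = {"frame_id", "level", "config_a", "config_b"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"paired table missing columns: {sorted(missing)}")
    rows = []
    grouped = {level_from_name(name): g for name, g in table.groupby("level")}
    for lvl in LEVELS:
        if lvl not in grouped:
            raise ValueError(f"paired table has no rows for level {lvl.name}")
        g = grouped[lvl]
        samples = PairedLevelSamples(
            level=lvl,
            a=tuple(float(x) for x in g["config_a"]),
            b=tuple(float(x) for x in g["config_b"]),
        )
        try:
            res = wilcoxon_signed_rank(samples)
            rows.append(
                dict(
                    level=lvl.name,
                    n_pairs=res.n_pairs,
                    statistic=res.statistic,
                    z=res.z_value,
                    p=res.p_value,
                    p_adjusted=res.p_adjusted,
                    r=res.effect_size_r,
                    significant=res.significant,
                    method=res.method,
                )
            )
        except DegenerateTestError:
            rows.append(
                dict(
                    level=lvl.name,
                    n_pairs=samples.n_pairs,
                    statistic=np.nan,
                    z=np.nan,
                    p=np.nan,
                    p_adjusted=np.nan,
                    r=np.nan,
                    significant=False,
                    method="degenerate",
                )
            )
    return pd.DataFrame(rows)
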