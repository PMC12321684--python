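"""Validation statistics for the rivalry scores.

Covers the analyses used to validate the improved priming score: Pearson
correlations with pairwise deletion of undefined scores, Steiger's test for
two dependent correlations sharing a criterion variable, the explained
variance ratio, Welch's t with Hedges' g for group contrasts, a median-split
analysis over the non-mixed trial count, and a DerSimonian-Laird
random-effects meta-analysis of correlation coefficients on the Fisher-z
scale.

Undefined (``None``/NaN) entries are always dropped pairwise and the
effective n used is reported alongside each statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.meta_analysis import combine_effects

from .scoring import ScoreBundle

__all__ = [
    "EffectSize",
    "MetaResult",
    "CorrComparison",
    "MedianSplitResult",
    "SubsetReport",
    "pearson",
    "compare_dependent_correlations",
    "variance_ratio",
    "dl_meta",
    "median_split_analysis",
    "group_compare",
    "one_sample_t",
]


# ---------------------------------------------------------------------------
# basic correlation machinery


def _complete_pairs(x: Sequence, y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Drop pairs where either entry is None/NaN."""
    xa = np.array([np.nan if v is None else float(v) for v in x])
    ya = np.array([np.nan if v is None else float(v) for v in y])
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    return xa[keep], ya[keep]


def pearson(x: Sequence, y: Sequence) -> tuple[Optional[float], int]:
    """Product-moment correlation on complete pairs.

    Returns ``(r, n)`` with ``n`` the effective pair count after pairwise
    deletion.  ``r`` is ``None`` when either variable has zero variance.

    Raises
    ------
    ValueError
        if fewer than 3 complete pairs remain.
    """
    xa, ya = _complete_pairs(x, y)
    n = len(xa)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return None, n
    r = float(sps.pearsonr(xa, ya).statistic)
    return r, n


# ---------------------------------------------------------------------------
# Steiger's test for dependent correlations


@dataclass(frozen=True)
class CorrComparison:
    """Result of comparing two dependent correlations sharing one variable."""

    z: float
    p: float
    tails: str  # "one" or "two"
    n: int


def compare_dependent_correlations(
    r_y1: float,
    r_y2: float,
    r_12: float,
    n: int,
    tails: str = "one",
) -> CorrComparison:
    """Steiger's Z for H0: rho(y,1) = rho(y,2) with 1 and 2 measured on the
    same sample (the two predictors correlate r_12).

    Uses Fisher-transformed correlations and Steiger's pooled-correlation
    estimate of their covariance.  ``tails="one"`` (default) reports
    P(Z > z), the probability that the first correlation exceeds the second
    by chance; positive z means r_y1 > r_y2.

    Raises
    ------
    ValueError
        if n < 10, any correlation is outside (-1, 1), or the three
        correlations do not form a positive semidefinite matrix.
    """
    if n < 10:
        raise ValueError(f"need n >= 10, got {n}")
    for name, r in (("r_y1", r_y1), ("r_y2", r_y2), ("r_12", r_12)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    corr = np.array([[1.0, r_y1, r_y2], [r_y1, 1.0, r_12], [r_y2, r_12, 1.0]])
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("correlations do not form a positive semidefinite matrix")

    z1 = math.atanh(r_y1)
    z2 = math.atanh(r_y2)
    rbar = 0.5 * (r_y1 + r_y2)
    rb2 = rbar * rbar
    # covariance of the two Fisher z's (Steiger's pooled-estimate form)
    cov = (r_12 * (1.0 - 2.0 * rb2) - 0.5 * rb2 * (1.0 - 2.0 * rb2 - r_12 * r_12)) / (
        (1.0 - rb2) ** 2
    )
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 - 2.0 * cov))
    if tails == "one":
        p = float(sps.norm.sf(z))
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return CorrComparison(z=float(z), p=p, tails=tails, n=n)


def variance_ratio(r2_baseline: float, r2_improved: float) -> float:
    """Ratio of explained variances R²_improved / R²_baseline."""
    if r2_baseline <= 0:
        raise ValueError("baseline R² must be positive")
    return r2_improved / r2_baseline


# ---------------------------------------------------------------------------
# DerSimonian-Laird random-effects meta-analysis of correlations


@dataclass(frozen=True)
class EffectSize:
    """One study's correlation and sample size."""

    study_id: str
    r: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 < self.r < 1.0:
            raise ValueError(f"r must lie strictly inside (-1, 1), got {self.r}")
        if self.n < 4:
            raise ValueError(f"n must be >= 4 for 1/(n-3) variance, got {self.n}")


@dataclass(frozen=True)
class MetaResult:
    pooled_r: float
    ci_low: float
    ci_high: float
    Q: float
    df: int
    I2: float
    tau2: float
    k: int
    excluded: tuple[str, ...] = ()
    table: pd.DataFrame = field(default=None, repr=False, compare=False)


def _dl_fit(effects: Sequence[EffectSize], alpha: float = 0.05):
    z = np.array([math.atanh(e.r) for e in effects])
    v = np.array([1.0 / (e.n - 3) for e in effects])
    with np.errstate(divide="ignore", invalid="ignore"):
        # combine_effects emits benign divide-by-zero warnings when Q == 0
        res = combine_effects(z, v, method_re="dl")
    tau2 = max(0.0, float(res.tau2))  # DL moment estimate truncated at zero
    w_fe = 1.0 / v
    mu_fe = float(np.sum(w_fe * z) / np.sum(w_fe))
    Q = float(np.sum(w_fe * (z - mu_fe) ** 2))
    dfq = len(effects) - 1
    w_re = 1.0 / (v + tau2)
    mu = float(np.sum(w_re * z) / np.sum(w_re))
    se = math.sqrt(1.0 / np.sum(w_re))
    crit = float(sps.norm.ppf(1 - alpha / 2))
    resid = (z - mu) / np.sqrt(v + tau2)
    return z, v, tau2, Q, dfq, mu, se, crit, resid, w_re


def dl_meta(
    effects: Iterable[EffectSize],
    residual_threshold: Optional[float] = None,
    alpha: float = 0.05,
) -> MetaResult:
    """Pool study correlations with the DerSimonian-Laird estimator.

    Correlations are Fisher-transformed with within-study variance
    ``1/(n - 3)``; the moment-based between-study variance tau² feeds
    inverse-variance weights, and the pooled Fisher z is back-transformed to
    r with its confidence interval.  Heterogeneity is summarised by Cochran's
    Q (df = k - 1) and I² = max(0, (Q - df)/Q) · 100.

    ``residual_threshold`` turns on influence exclusion: studies whose
    standardized residual ``(z_i - mu)/sqrt(v_i + tau²)`` exceeds the
    threshold in magnitude are removed one at a time (largest first, pooled
    estimate recomputed after each removal) until none exceed it or only two
    studies remain.
    """
    pool = list(effects)
    if len(pool) < 2:
        raise ValueError(f"need >= 2 studies, got {len(pool)}")

    excluded: list[str] = []
    while True:
        z, v, tau2, Q, dfq, mu, se, crit, resid, w_re = _dl_fit(pool, alpha)
        if residual_threshold is None or len(pool) <= 2:
            break
        worst = int(np.argmax(np.abs(resid)))
        if abs(resid[worst]) <= residual_threshold:
            break
        excluded.append(pool[worst].study_id)
        del pool[worst]

    weights = w_re / w_re.sum()
    table = pd.DataFrame(
        {
            "study_id": [e.study_id for e in pool],
            "r": [e.r for e in pool],
            "n": [e.n for e in pool],
            "ci_low": np.tanh(z - crit * np.sqrt(v)),
            "ci_high": np.tanh(z + crit * np.sqrt(v)),
            "weight": weights,
            "std_residual": resid,
        }
    )
    return MetaResult(
        pooled_r=float(math.tanh(mu)),
        ci_low=float(math.tanh(mu - crit * se)),
        ci_high=float(math.tanh(mu + crit * se)),
        Q=Q,
        df=dfq,
        I2=float(max(0.0, (Q - dfq) / Q) * 100.0) if Q > 0 else 0.0,
        tau2=tau2,
        k=len(pool),
        excluded=tuple(excluded),
        table=table,
    )


# ---------------------------------------------------------------------------
# group comparison and median split


def group_compare(a: Sequence, b: Sequence) -> tuple[float, float, float, float]:
    """Welch's unequal-variance t-test plus Hedges' g.

    Returns ``(t, df, p, g)`` with Welch-Satterthwaite degrees of freedom and
    two-sided p.  g is the pooled-SD standardized mean difference with the
    small-sample bias correction ``1 - 3/(4(n1 + n2) - 9)``.
    """
    xa = np.asarray([v for v in a if v is not None and not np.isnan(v)], dtype=float)
    xb = np.asarray([v for v in b if v is not None and not np.isnan(v)], dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(xa) == 0 and np.ptp(xb) == 0:
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind(xa, xb, equal_var=False)
    n1, n2 = len(xa), len(xb)
    s1, s2 = xa.var(ddof=1), xb.var(ddof=1)
    s_pooled = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    d = (xa.mean() - xb.mean()) / s_pooled
    g = d * (1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0))
    return float(res.statistic), float(res.df), float(res.pvalue), float(g)


def one_sample_t(x: Sequence, popmean: float = 0.0) -> tuple[float, int, float]:
    """One-sample t against ``popmean`` (undefined entries dropped);
    returns (t, df, two-sided p).  Used e.g. for the cohort-level test of the
    mock-trial imagery-consistency bias against zero."""
    xa = np.asarray([v for v in x if v is not None and not np.isnan(v)], dtype=float)
    if len(xa) < 2:
        raise ValueError("need n >= 2 defined values")
    res = sps.ttest_1samp(xa, popmean)
    return float(res.statistic), len(xa) - 1, float(res.pvalue)


@dataclass(frozen=True)
class SubsetReport:
    n: int
    r_original: float
    r_improved: float
    comparison: CorrComparison


@dataclass(frozen=True)
class MedianSplitResult:
    split_on: str
    median: float
    low: SubsetReport
    high: SubsetReport


def median_split_analysis(
    bundles: Sequence[ScoreBundle],
    vviq: Sequence,
    split_on: str = "n_nonmixed",
    tails: str = "one",
) -> MedianSplitResult:
    """Split participants at the median of a score-bundle field and compare,
    within each subset, how well the original vs improved priming score
    correlates with VVIQ (Steiger comparison, improved minus original).

    Ties at the median go to the low subset.  Participants whose split field,
    either priming score, or VVIQ is undefined are dropped.
    """
    if len(bundles) != len(vviq):
        raise ValueError("bundles and vviq must have equal length")
    rows = [
        (getattr(b, split_on), b.original, b.improved, y)
        for b, y in zip(bundles, vviq)
        if getattr(b, split_on) is not None
        and b.original is not None
        and b.improved is not None
        and y is not None
        and not np.isnan(float(y))
    ]
    if not rows:
        raise ValueError("no complete participants to split")
    split_vals = np.array([r[0] for r in rows], dtype=float)
    med = float(np.median(split_vals))
    low_rows = [r for r in rows if r[0] <= med]
    high_rows = [r for r in rows if r[0] > med]
    if not low_rows or not high_rows:
        raise ValueError(f"degenerate split on {split_on!r}: one side is empty")

    def _report(subset) -> SubsetReport:
        orig = [r[1] for r in subset]
        impr = [r[2] for r in subset]
        y = [r[3] for r in subset]
        r_orig, n_eff = pearson(orig, y)
        r_impr, _ = pearson(impr, y)
        r_oi, _ = pearson(orig, impr)
        if r_orig is None or r_impr is None or r_oi is None:
            raise ValueError("zero-variance subset; cannot compare correlations")
        cmp_ = compare_dependent_correlations(r_impr, r_orig, r_oi, n_eff, tails=tails)
        return SubsetReport(n=n_eff, r_original=r_orig, r_improved=r_impr, comparison=cmp_)

    return MedianSplitResult(
        split_on=split_on, median=med, low=_report(low_rows), high=_report(high_rows)
    )
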