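"""Longitudinal statistics for the visit design: distribution screening,
paired visit comparisons, adult-vs-children group comparisons and
correlation.

The procedure mirrors common practice in small clinical cohorts:
Kolmogorov-Smirnov (with Lilliefors correction for estimated parameters)
for normality, Levene for homogeneity of variances, Wilcoxon signed-rank
for paired visit contrasts (vt0 vs vt3, vt0 vs vt12) on
pairwise-complete participants, one-way ANOVA for the two-arm contrast
(with two groups F = t^2), and Pearson correlation; skewed variables are
log-transformed first. Significance is read at p < 0.05, but p-values are
always reported numerically, never collapsed to a verdict.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DistributionScreen", "ComparisonResult", "screen_distribution",
    "log_transform", "paired_visit_test", "group_test", "correlate",
    "adjust_pvalues",
]

ALPHA = 0.05


@dataclass
class DistributionScreen:
    normal: Optional[bool]          # None when undefined (constant input)
    homogeneous: Optional[bool]
    skewed: bool
    ks_p: Optional[float] = None
    levene_p: Optional[float] = None
    skewness: Optional[float] = None
    degenerate: bool = False


@dataclass
class ComparisonResult:
    variable: str
    contrast: str                   # vt0_vs_vt3 | vt0_vs_vt12 | adults_vs_children_at_visit
    n: int                          # pairs, or total across groups
    statistic: Optional[float]
    p_value: Optional[float]
    transform_applied: bool = False
    flag: Optional[str] = None      # "underpowered" | "all_ties" | None


def screen_distribution(values: Sequence[float],
                        groups: Optional[Sequence[Sequence[float]]] = None,
                        alpha: float = ALPHA,
                        lilliefors_correction: bool = True) -> DistributionScreen:
    """Normality (KS), homogeneity (Levene, when groups given) and skew.

    The KS test uses the Lilliefors correction by default since the normal
    parameters are estimated from the sample; set
    ``lilliefors_correction=False`` for the fully specified KS test
    against the fitted normal. |sample skewness| > 1 flags a variable as
    skewed (candidate for log transform).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        return DistributionScreen(normal=None, homogeneous=None, skewed=False,
                                  degenerate=True)
    if lilliefors_correction:
        _, ks_p = lilliefors(x, dist="norm")
    else:
        _, ks_p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    skewness = float(sps.skew(x, bias=False))
    lev_p = None
    homogeneous = None
    if groups is not None and len(groups) >= 2:
        _, lev_p = sps.levene(*[np.asarray(g, dtype=float) for g in groups])
        homogeneous = bool(lev_p >= alpha)
    return DistributionScreen(normal=bool(ks_p >= alpha),
                              homogeneous=homogeneous,
                              skewed=bool(abs(skewness) > 1.0), ks_p=float(ks_p),
                              levene_p=None if lev_p is None else float(lev_p),
                              skewness=skewness)


def log_transform(values: Sequence[float]) -> np.ndarray:
    """Natural log; when zeros are present an offset of half the smallest
    positive value is added first. Negative values are not transformable."""
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("log transform undefined for negative values")
    if (x == 0).any():
        pos = x[x > 0]
        if len(pos) == 0:
            raise ValueError("log transform undefined for all-zero input")
        x = x + pos.min() / 2.0
    return np.log(x)


def paired_visit_test(values_a: Sequence[float], values_b: Sequence[float],
                      ids_a: Sequence[str], ids_b: Sequence[str],
                      variable: str = "", contrast: str = "vt0_vs_vt3",
                      min_pairs: int = 5) -> ComparisonResult:
    """Wilcoxon signed-rank on pairwise-complete participants.

    Participants are matched by id; zero differences are dropped (the
    classic Wilcoxon convention); the exact null distribution is used for
    n <= 25 non-zero pairs, the normal approximation with tie-corrected
    variance otherwise. Fewer than ``min_pairs`` complete pairs yields an
    underpowered result without a p-value.
    """
    a_by = dict(zip(ids_a, values_a))
    b_by = dict(zip(ids_b, values_b))
    common = sorted(set(a_by) & set(b_by))
    d = np.array([b_by[i] - a_by[i] for i in common], dtype=float)
    n_pairs = len(d)
    if n_pairs < min_pairs:
        return ComparisonResult(variable, contrast, n_pairs, None, None,
                                flag="underpowered")
    nz = d[d != 0]
    if len(nz) == 0:
        return ComparisonResult(variable, contrast, n_pairs, None, 1.0,
                                flag="all_ties")
    method = "exact" if len(nz) <= 25 else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", method=method)
    # signed statistic: positive when b tends to exceed a
    w_plus = float(np.sum(sps.rankdata(np.abs(nz))[nz > 0]))
    w_minus = float(np.sum(sps.rankdata(np.abs(nz))[nz < 0]))
    return ComparisonResult(variable, contrast, n_pairs,
                            statistic=w_plus - w_minus,
                            p_value=float(res.pvalue))


def group_test(adult_values: Sequence[float], child_values: Sequence[float],
               variable: str = "", transform: str = "auto") -> ComparisonResult:
    """One-way ANOVA between the two arms (two groups, so F = t^2).

    ``transform="auto"`` log-transforms both groups when the pooled sample
    is skewed (|skewness| > 1); "log" forces it; "none" disables it.
    """
    a = np.asarray(adult_values, dtype=float)
    c = np.asarray(child_values, dtype=float)
    if len(a) < 3 or len(c) < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(a) == 0 and np.ptp(c) == 0:
        raise ValueError("zero variance in both groups")
    applied = False
    if transform == "log" or (
            transform == "auto"
            and abs(sps.skew(np.concatenate([a, c]), bias=False)) > 1.0
            and (np.concatenate([a, c]) >= 0).all()):
        pooled = log_transform(np.concatenate([a, c]))
        a, c = pooled[:len(a)], pooled[len(a):]
        applied = True
    f, p = sps.f_oneway(a, c)
    return ComparisonResult(variable, "adults_vs_children_at_visit",
                            n=len(a) + len(c), statistic=float(f),
                            p_value=float(p), transform_applied=applied)


def correlate(x: Sequence[float], y: Sequence[float],
              transform: str = "auto") -> dict:
    """Pearson correlation with two-sided p; skewed inputs (|skewness| > 1,
    non-negative) are log-transformed first."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya) or len(xa) < 4:
        raise ValueError("need n >= 4 paired finite values")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("non-finite values")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance input")
    applied = False
    if transform in ("auto", "log"):
        def maybe(v):
            nonlocal applied
            if transform == "log" or (abs(sps.skew(v, bias=False)) > 1.0
                                      and (v >= 0).all()):
                applied = True
                return log_transform(v)
            return v
        xa, ya = maybe(xa), maybe(ya)
    r, p = sps.pearsonr(xa, ya)
    return {"r": float(r), "p": float(p), "n": len(xa),
            "transform_applied": applied}


def adjust_pvalues(pvalues: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Optional multiple-testing adjustment (off by default everywhere,
    matching the single-comparison reporting convention of small dietary
    studies); Benjamini-Hochberg by default when invoked."""
    return multipletests(list(pvalues), method=method)[1]
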