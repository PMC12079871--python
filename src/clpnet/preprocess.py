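"""Descriptive statistics, mean comparisons, and the nonparanormal transform.

Descriptives and paired tests are computed on the *raw* ordinal responses;
the rank-based Gaussianization in :func:`nonparanormal_transform` is applied
only afterwards, immediately before network estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import PanelDataset

__all__ = [
    "DescriptiveRow",
    "PairedComparison",
    "IndependentComparison",
    "descriptive_table",
    "descriptives_frame",
    "paired_comparison",
    "paired_table",
    "attrition_comparison",
    "nonparanormal_transform",
    "transform_dataset",
    "cronbach_alpha",
]

#: screening rule for severe non-normality of an item distribution
SKEW_FLAG = 2.0
KURT_FLAG = 7.0


@dataclass(frozen=True)
class DescriptiveRow:
    node_id: str
    wave: str
    mean: float
    sd: float
    skewness: float  # bias-adjusted (G1)
    kurtosis: float  # bias-adjusted excess (G2)
    normality_flag: bool  # True when |skew| > 2 or |kurtosis| > 7


@dataclass(frozen=True)
class PairedComparison:
    node_id: str
    t_statistic: float
    p_value: float
    mean_difference: float
    difference_ci: tuple[float, float]
    cohens_d: float
    d_ci: tuple[float, float]


@dataclass(frozen=True)
class IndependentComparison:
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    n = len(x)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        warnings.warn("constant column: skewness/kurtosis undefined",
                      RuntimeWarning, stacklevel=3)
        return mean, 0.0, np.nan, np.nan
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, bias=False))
    return mean, sd, skew, kurt


def descriptive_table(dataset: PanelDataset) -> list[DescriptiveRow]:
    """Per-node, per-wave mean/SD/skewness/kurtosis with normality flags.

    Skewness and excess kurtosis use the small-sample bias-adjusted
    estimators (the G1/G2 conventions of mainstream statistics packages).
    A constant column reports SD 0 and NaN shape statistics with a warning.
    """
    rows: list[DescriptiveRow] = []
    for wave, mat in (("t1", dataset.wave1), ("t2", dataset.wave2)):
        for j, node in enumerate(dataset.nodes):
            mean, sd, skew, kurt = _moments(mat[:, j])
            flag = bool(np.isfinite(skew) and np.isfinite(kurt) and
                        (abs(skew) > SKEW_FLAG or abs(kurt) > KURT_FLAG))
            rows.append(DescriptiveRow(node.id, wave, mean, sd, skew, kurt,
                                       flag))
    return rows


def descriptives_frame(rows: list[DescriptiveRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def paired_comparison(x1: np.ndarray, x2: np.ndarray,
                      node_id: str = "", confidence: float = 0.95
                      ) -> PairedComparison:
    """Paired t-test of wave-2 minus wave-1 scores for one node.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = x2 - x1`` and ``n - 1``
    degrees of freedom; Cohen's d for paired data is ``mean(d)/sd(d)``.  The
    mean-difference CI is the exact t interval; the d CI uses the normal
    approximation with ``SE = sqrt(1/n + d^2/(2n))``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1 or len(x1) < 3:
        raise ValueError("paired_comparison needs two equal-length vectors, n >= 3")
    d = x2 - x1
    n = len(d)
    md = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    if sd_d == 0.0:
        if md != 0.0:
            raise ValueError(
                "degenerate paired comparison: constant nonzero difference")
        return PairedComparison(node_id, 0.0, 1.0, 0.0, (0.0, 0.0), 0.0,
                                (0.0, 0.0))
    se = sd_d / np.sqrt(n)
    t = md / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    ci = (md - tcrit * se, md + tcrit * se)
    cohens_d = md / sd_d
    se_d = np.sqrt(1.0 / n + cohens_d ** 2 / (2.0 * n))
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    d_ci = (cohens_d - z * se_d, cohens_d + z * se_d)
    return PairedComparison(node_id, float(t), float(p), md,
                            (float(ci[0]), float(ci[1])), float(cohens_d),
                            (float(d_ci[0]), float(d_ci[1])))


def paired_table(dataset: PanelDataset) -> list[PairedComparison]:
    """Paired comparisons T2 vs T1 for every node."""
    return [paired_comparison(dataset.wave1[:, j], dataset.wave2[:, j],
                              node_id=node.id)
            for j, node in enumerate(dataset.nodes)]


def paired_frame(rows: list[PairedComparison]) -> pd.DataFrame:
    recs = []
    for r in rows:
        recs.append({
            "node_id": r.node_id, "t": r.t_statistic, "p": r.p_value,
            "difference": r.mean_difference,
            "diff_ci_low": r.difference_ci[0], "diff_ci_high": r.difference_ci[1],
            "cohens_d": r.cohens_d,
            "d_ci_low": r.d_ci[0], "d_ci_high": r.d_ci[1],
        })
    return pd.DataFrame(recs)


def attrition_comparison(completers: np.ndarray, dropouts: np.ndarray
                         ) -> IndependentComparison:
    """Welch independent-samples t-test comparing completers vs dropouts."""
    a = np.asarray(completers, dtype=float)
    b = np.asarray(dropouts, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("attrition comparison needs >= 2 subjects per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return IndependentComparison(float(t), float(p), float(np.mean(a)),
                                 float(np.mean(b)))


def _npn_delta(n: int) -> float:
    # Winsorization level for the truncated empirical CDF
    return 1.0 / (4.0 * n ** 0.25 * np.sqrt(np.pi * np.log(n)))


def nonparanormal_transform(matrix: np.ndarray) -> np.ndarray:
    """Column-wise rank-based Gaussianization (nonparanormal transform).

    Each column's average-rank empirical CDF ``rank/n`` is Winsorized to
    ``[delta_n, 1 - delta_n]`` with ``delta_n = 1/(4 n^{1/4} sqrt(pi log n))``
    and mapped through the standard-normal quantile function; the result is
    rescaled to unit sample variance (ddof=1).  The map is strictly monotone
    on distinct values, so Spearman correlations are preserved exactly.

    A constant column maps to all zeros (every rank ties at the median) with
    a warning.
    """
    X = np.asarray(matrix, dtype=float)
    one_dim = X.ndim == 1
    if one_dim:
        X = X[:, None]
    n = X.shape[0]
    if n < 4:
        raise ValueError("nonparanormal transform needs n >= 4")
    delta = _npn_delta(n)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0.0:
            warnings.warn(f"constant column {j}: transformed to zeros",
                          RuntimeWarning, stacklevel=2)
            out[:, j] = 0.0
            continue
        ranks = stats.rankdata(col, method="average")
        u = np.clip(ranks / n, delta, 1.0 - delta)
        z = stats.norm.ppf(u)
        out[:, j] = z / np.std(z, ddof=1)
    return out[:, 0] if one_dim else out


def transform_dataset(dataset: PanelDataset) -> PanelDataset:
    """Nonparanormal-transform both waves' node columns; covariates untouched."""
    return replace(
        dataset,
        wave1=nonparanormal_transform(dataset.wave1),
        wave2=nonparanormal_transform(dataset.wave2),
        transformed=True,
    )


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha for a subjects x items response matrix."""
    X = np.asarray(items, dtype=float)
    k = X.shape[1]
    if k < 2:
        raise ValueError("alpha needs >= 2 items")
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def percentage(count: float, total: float, decimals: int = 1) -> float:
    """Share of a total expressed in percent, e.g. follow-up retention."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)
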