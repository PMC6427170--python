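"""Statistical battery for exposure-uncertainty analysis.

Given the addresses x (year, radius) exposure matrix, this module quantifies
how much residential green-space exposure depends on *when* it is measured
(year of imagery) and on *how* the spatial context is delimited (buffer
radius):

* descriptive summaries per (radius, year) column, including moment-based
  skewness and excess kurtosis;
* the Spearman rank-correlation matrix across all year x radius columns, with
  Holm-adjusted significance;
* pairwise two-sample Wilcoxon rank-sum tests between years within a radius,
  Holm-adjusted within that radius's family of year pairs;
* Fligner–Killeen tests of variance homogeneity across years;
* an ordinary least-squares trend of annual mean exposure on calendar year.

All tests are two-sided.  Rank-based procedures are used throughout because
exposure distributions are typically skewed and heavy-shouldered; p-values
are stored at full precision (display rounding is a formatting concern only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# descriptive summaries


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    min: float
    max: float
    skewness: float  # g1 = m3 / m2^(3/2); NaN when variance is zero
    kurtosis: float  # excess, g2 = m4 / m2^2 - 3; NaN when variance is zero


def summarize(values) -> SummaryStats:
    """Moment and order-statistic summary of one exposure sample.

    Skewness and kurtosis are the moment estimators built from central
    moments with the 1/n divisor (kurtosis in excess form, so a normal sample
    scores near 0); the standard deviation uses the n-1 divisor; quartiles
    interpolate linearly between order statistics.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty sample after dropping missing values")
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        skew = kurt = float("nan")
    else:
        skew = float(sps.skew(x, bias=True))
        kurt = float(sps.kurtosis(x, fisher=True, bias=True))
    return SummaryStats(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        q25=float(np.percentile(x, 25)),
        q75=float(np.percentile(x, 75)),
        min=float(x.min()),
        max=float(x.max()),
        skewness=skew,
        kurtosis=kurt,
    )


def summary_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """One summary row per (radius, year) column, largest radius first."""
    rows = []
    radii = sorted({r for _, r in matrix.columns}, reverse=True)
    years = sorted({y for y, _ in matrix.columns})
    for radius in radii:
        for year in years:
            s = summarize(matrix[(year, radius)])
            rows.append({"buffer_m": radius, "year": year, **s.__dict__})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple testing


def holm_adjust(pvals) -> np.ndarray:
    """Holm's step-down familywise-error adjustment.

    Sort ascending; the i-th smallest becomes
    ``max_{j<=i} min(1, (m - j + 1) * p_(j))``; return in input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(stepped)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


# ---------------------------------------------------------------------------
# Spearman correlation matrix


@dataclass(frozen=True)
class CorrelationMatrix:
    labels: tuple  # (year, radius) column labels
    rho: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray  # Holm over all unique off-diagonal pairs

    def to_frames(self) -> dict[str, pd.DataFrame]:
        names = [f"{int(y)}_{int(r)}" for y, r in self.labels]
        return {
            "rho": pd.DataFrame(self.rho, index=names, columns=names),
            "p_raw": pd.DataFrame(self.p_raw, index=names, columns=names),
            "p_adj": pd.DataFrame(self.p_adj, index=names, columns=names),
        }


def spearman_matrix(matrix: pd.DataFrame, min_n: int = 3) -> CorrelationMatrix:
    """Spearman rho (mid-ranks for ties) between every pair of columns.

    Missing values are deleted pairwise.  Two-sided p-values come from the
    t-approximation on n-2 degrees of freedom; Holm adjustment runs over the
    full family of unique off-diagonal pairs.  A constant column has no
    defined rank correlation: its entries are NaN and a warning is issued.
    """
    labels = tuple(matrix.columns)
    k = len(labels)
    rho = np.eye(k)
    p_raw = np.zeros((k, k))
    vals = matrix.to_numpy(dtype=float)
    for i, j in combinations(range(k), 2):
        ok = ~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])
        xi, xj = vals[ok, i], vals[ok, j]
        if ok.sum() < min_n:
            raise ValueError(
                f"columns {labels[i]} / {labels[j]}: only {int(ok.sum())} complete pairs"
            )
        if np.ptp(xi) == 0 or np.ptp(xj) == 0:
            warnings.warn(
                f"constant column among {labels[i]}, {labels[j]}; correlation undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            r, p = float("nan"), float("nan")
        else:
            r, p = sps.spearmanr(xi, xj)
        rho[i, j] = rho[j, i] = r
        p_raw[i, j] = p_raw[j, i] = p
    iu = np.triu_indices(k, 1)
    flat = p_raw[iu]
    defined = ~np.isnan(flat)
    adj_flat = np.full_like(flat, np.nan)
    if defined.any():
        adj_flat[defined] = holm_adjust(flat[defined])
    p_adj = np.zeros((k, k))
    p_adj[iu] = adj_flat
    p_adj = p_adj + p_adj.T
    return CorrelationMatrix(labels=labels, rho=rho, p_raw=p_raw, p_adj=p_adj)


# ---------------------------------------------------------------------------
# rank-sum tests


def wilcoxon_rank_sum(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test; returns (W, two-sided p).

    ``W`` is the mid-rank sum of the first sample in the pooled ranking.  The
    p-value uses the normal approximation with tie-corrected variance and a
    0.5 continuity correction, except that small untied problems
    (``na + nb <= 10``, ``method="auto"``) are solved by exact enumeration of
    all allocations of ranks to the first sample.  ``method`` may force
    "exact" or "asymptotic".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty after dropping missing")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (a.size + b.size <= 10 and not has_ties) else "asymptotic"
    if method == "exact" and has_ties:
        raise ValueError("exact enumeration requires tie-free samples")
    if method not in ("exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    return w, float(res.pvalue)


@dataclass(frozen=True)
class PairwiseTestMatrix:
    radius: float
    pairs: tuple  # (year_i, year_j) with year_i < year_j
    p_raw: np.ndarray
    p_adj: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year_a": [a for a, _ in self.pairs],
                "year_b": [b for _, b in self.pairs],
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
            }
        )


def pairwise_year_tests(
    matrix: pd.DataFrame,
    radius: float,
    paired: bool = False,
    family: str = "radius",
) -> PairwiseTestMatrix:
    """Wilcoxon tests between every unordered pair of years at one radius.

    The default (and literal) reading is the unpaired rank-sum test, even
    though year columns share addresses; ``paired=True`` switches to the
    signed-rank test on per-address differences.  Holm adjustment runs within
    this radius's family of year pairs (``family="radius"``); with
    ``family="none"`` the raw values are returned unadjusted so a caller can
    pool families across radii before adjusting globally.
    """
    years = sorted({y for y, _ in matrix.columns})
    if len(years) < 2:
        raise ValueError("need at least two years")
    radius = float(radius)
    pairs = list(combinations(years, 2))
    p_raw = np.empty(len(pairs))
    for k, (ya, yb) in enumerate(pairs):
        xa = matrix[(ya, radius)].to_numpy(dtype=float)
        xb = matrix[(yb, radius)].to_numpy(dtype=float)
        if paired:
            ok = ~np.isnan(xa) & ~np.isnan(xb)
            d = xa[ok] - xb[ok]
            if np.all(d == 0):
                p = 1.0
            else:
                p = float(sps.wilcoxon(xa[ok], xb[ok]).pvalue)
        else:
            _, p = wilcoxon_rank_sum(xa, xb, method="asymptotic")
        p_raw[k] = p
    if family == "radius":
        p_adj = holm_adjust(p_raw)
    elif family == "none":
        p_adj = p_raw.copy()
    else:
        raise ValueError(f"unknown family scope {family!r}")
    return PairwiseTestMatrix(
        radius=radius, pairs=tuple(pairs), p_raw=p_raw, p_adj=p_adj
    )


def pairwise_all_radii(
    matrix: pd.DataFrame, paired: bool = False, family: str = "radius"
) -> dict[float, PairwiseTestMatrix]:
    """Pairwise year tests for every radius; ``family="global"`` Holm-adjusts
    the pooled family of all radii's year pairs at once."""
    radii = sorted({r for _, r in matrix.columns})
    if family == "global":
        parts = {
            r: pairwise_year_tests(matrix, r, paired=paired, family="none")
            for r in radii
        }
        pooled = np.concatenate([parts[r].p_raw for r in radii])
        adj = holm_adjust(pooled)
        out = {}
        start = 0
        for r in radii:
            t = parts[r]
            out[r] = PairwiseTestMatrix(
                radius=t.radius,
                pairs=t.pairs,
                p_raw=t.p_raw,
                p_adj=adj[start : start + len(t.pairs)],
            )
            start += len(t.pairs)
        return out
    return {
        r: pairwise_year_tests(matrix, r, paired=paired, family=family) for r in radii
    }


# ---------------------------------------------------------------------------
# variance homogeneity


@dataclass(frozen=True)
class VarianceTestResult:
    grouping: str
    statistic: float
    df: int
    pvalue: float


def fligner_killeen(groups, grouping: str = "") -> VarianceTestResult:
    """Fligner–Killeen k-sample test of equal variances.

    Absolute deviations from each group's median are jointly mid-ranked and
    transformed to normal scores a_i = Phi^{-1}(1/2 + r_i / (2(N+1))); the
    chi-square statistic compares group mean scores, with k-1 degrees of
    freedom.  Robust to non-normal group distributions.
    """
    cleaned = []
    for g in groups:
        x = np.asarray(g, dtype=float)
        x = x[~np.isnan(x)]
        if x.size < 2:
            raise ValueError("every group needs at least 2 non-missing values")
        cleaned.append(x)
    if len(cleaned) < 2:
        raise ValueError("need at least two groups")
    stat, p = sps.fligner(*cleaned)
    return VarianceTestResult(
        grouping=grouping, statistic=float(stat), df=len(cleaned) - 1, pvalue=float(p)
    )


def fligner_by_year(matrix: pd.DataFrame) -> pd.DataFrame:
    """Across-year variance-homogeneity test within each radius."""
    years = sorted({y for y, _ in matrix.columns})
    rows = []
    for radius in sorted({r for _, r in matrix.columns}):
        groups = [matrix[(y, radius)].dropna().to_numpy() for y in years]
        res = fligner_killeen(groups, grouping=f"years within {int(radius)} m")
        rows.append(
            {
                "buffer_m": radius,
                "statistic": res.statistic,
                "df": res.df,
                "pvalue": res.pvalue,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# temporal trend


def annual_trend(matrix: pd.DataFrame, radius: float) -> tuple[float, float]:
    """OLS fit of annual mean exposure on calendar year -> (slope, intercept).

    Slope is in NDVI units per year; this is the regression line drawn
    through per-year means, not through address-level points.
    """
    radius = float(radius)
    years = sorted({y for y, _ in matrix.columns})
    if len(years) < 2:
        raise ValueError("need at least two years for a trend")
    means = np.array([matrix[(y, radius)].mean(skipna=True) for y in years])
    slope, intercept = np.polyfit(np.asarray(years, dtype=float), means, 1)
    return float(slope), float(intercept)


def trend_table(matrix: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for radius in sorted({r for _, r in matrix.columns}):
        slope, intercept = annual_trend(matrix, radius)
        rows.append({"buffer_m": radius, "slope_per_year": slope, "intercept": intercept})
    return pd.DataFrame(rows)
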