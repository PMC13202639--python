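"""Cohort-level statistical screen.

Univariate, two-sided throughout: Mann-Whitney U (exact by full enumeration
for small samples, normal approximation with tie and continuity corrections
otherwise), Bonferroni multiplicity correction over the screened feature
set, Cohen's d with the conventional small/medium/large bins (|d| < 0.5,
0.5-0.79, >= 0.8), region-grouped effect summaries, and Pearson correlation
of features against clinical covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .registry import FeatureRegistry, default_registry

__all__ = [
    "mann_whitney_u",
    "bonferroni_adjust",
    "cohens_d",
    "effect_category",
    "pearson_r",
    "CorrelationResult",
    "FeatureComparison",
    "RegionEffectSummary",
    "feature_screen",
    "correlate_with_clinical",
]

_EXACT_MAX_N = 12


def mann_whitney_u(
    x, y, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midranks for ties.

    Returns ``(U, p)`` where U is the smaller of the two rank-sum
    statistics.  ``mode``: ``"exact"`` enumerates all group labelings (the
    null permutation distribution of U, valid under ties); ``"normal_approx"``
    uses the tie-corrected normal approximation with continuity correction;
    ``"auto"`` picks exact when n_x + n_y <= 12.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    ux = float(np.sum(ranks[:nx]) - nx * (nx + 1) / 2)
    uy = nx * ny - ux
    u_min = min(ux, uy)
    mu = nx * ny / 2.0

    if np.ptp(pooled) == 0:
        return u_min, 1.0  # degenerate: all observations identical

    if mode == "auto":
        mode = "exact" if nx + ny <= _EXACT_MAX_N else "normal_approx"
    if mode == "exact":
        n = nx + ny
        dev_obs = abs(ux - mu)
        hits = total = 0
        for idx in combinations(range(n), nx):
            u = float(np.sum(ranks[list(idx)]) - nx * (nx + 1) / 2)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_min, hits / total
    if mode != "normal_approx":
        raise ValueError(f"unknown mode {mode!r}")
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_min, 1.0
    z = (abs(ux - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return u_min, float(2.0 * sps.norm.sf(z))


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    """min(1, p * m); m defaults to the number of tests supplied."""
    ps = list(p_values)
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps) if m is None else m
    return [min(1.0, p * m) for p in ps]


def cohens_d(x, y) -> float:
    """Standardized mean difference with the pooled (n-2) SD; signed."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (
        nx + ny - 2
    )
    diff = float(np.mean(x) - np.mean(y))
    if sp2 == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / math.sqrt(sp2)


def effect_category(d: float) -> str:
    """|d| < 0.5 small, 0.5 <= |d| < 0.8 medium, |d| >= 0.8 large."""
    a = abs(d)
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    covariate: str
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float


def pearson_r(
    x, y, feature: str = "x", covariate: str = "y"
) -> CorrelationResult:
    """Pearson product-moment correlation with the two-sided t-based p-value
    and the least-squares line (for regression-plot export)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    lin = sps.linregress(x, y)
    return CorrelationResult(
        feature=feature,
        covariate=covariate,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(x),
        slope=float(lin.slope),
        intercept=float(lin.intercept),
    )


@dataclass(frozen=True)
class FeatureComparison:
    feature: str
    region: str
    u_stat: float
    p_raw: float
    p_adj: float
    d: float                 # signed (group A minus group B)
    category: str            # from |d|
    n_a: int
    n_b: int


@dataclass
class RegionEffectSummary:
    """Counts and proportions of features per region and effect category."""

    table: pd.DataFrame

    @classmethod
    def from_comparisons(
        cls, comparisons: list[FeatureComparison]
    ) -> "RegionEffectSummary":
        rows = []
        regions = sorted({c.region for c in comparisons})
        for region in regions:
            sub = [c for c in comparisons if c.region == region]
            counts = {
                cat: sum(c.category == cat for c in sub)
                for cat in ("small", "medium", "large")
            }
            total = len(sub)
            row = {"region": region, "n_features": total}
            for cat in ("small", "medium", "large"):
                row[f"n_{cat}"] = counts[cat]
                row[f"pct_{cat}"] = 100.0 * counts[cat] / total
            rows.append(row)
        return cls(pd.DataFrame(rows))


def feature_screen(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    registry: FeatureRegistry | None = None,
    m: int | None = None,
    mode: str = "auto",
) -> tuple[list[FeatureComparison], RegionEffectSummary]:
    """Per-feature two-group screen (A vs B) over the registry's aggregated
    feature columns: Mann-Whitney U with Bonferroni correction (m = number
    of features screened unless given) and Cohen's d with its category,
    summarized by waveform region."""
    registry = registry or default_registry()
    names = [
        n for n in registry.vector_names
        if n in features_a.columns and n in features_b.columns
    ]
    if not names:
        raise ValueError("no registry features present in both tables")
    m = m if m is not None else len(names)
    comparisons: list[FeatureComparison] = []
    for name in names:
        a = features_a[name].dropna().to_numpy()
        b = features_b[name].dropna().to_numpy()
        u, p = mann_whitney_u(a, b, mode=mode)
        d = cohens_d(a, b)
        comparisons.append(
            FeatureComparison(
                feature=name,
                region=registry.region_of(name),
                u_stat=u,
                p_raw=p,
                p_adj=min(1.0, p * m),
                d=d,
                category=effect_category(d),
                n_a=len(a),
                n_b=len(b),
            )
        )
    return comparisons, RegionEffectSummary.from_comparisons(comparisons)


def correlate_with_clinical(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> list[CorrelationResult]:
    """Correlate per-subject feature medians against clinical covariates.

    ``features`` has one row per recording (keyed by ``subject_id``);
    recordings are collapsed to subject medians before joining with the
    subject-keyed covariate table.  Missing covariates are dropped pairwise;
    fewer than 3 complete pairs is an error for that pair.
    """
    results = []
    for feature, covariate in pairs:
        if feature not in features.columns:
            raise KeyError(f"feature {feature!r} not in feature table")
        if covariate not in covariates.columns:
            raise KeyError(f"covariate {covariate!r} not in covariate table")
        per_subject = (
            features.groupby("subject_id")[feature].median().rename(feature)
        )
        merged = pd.merge(
            per_subject.reset_index(),
            covariates[["subject_id", covariate]],
            on="subject_id",
            how="inner",
        ).dropna()
        if len(merged) < 3:
            raise ValueError(
                f"fewer than 3 complete pairs for ({feature}, {covariate})"
            )
        results.append(
            pearson_r(
                merged[feature].to_numpy(),
                merged[covariate].to_numpy(),
                feature=feature,
                covariate=covariate,
            )
        )
    return results
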