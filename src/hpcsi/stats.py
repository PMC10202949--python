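"""Group-comparison and association statistics for study tables.

Two test families mirror standard practice for four-arm animal studies:
one-way ANOVA with Tukey's HSD post-hoc correction, and Kruskal-Wallis
with pairwise comparisons corrected by the two-stage step-up FDR
procedure of Benjamini, Krieger and Yekutieli (2006, Definition 6).
Associations are Pearson correlations or simple linear regressions.

Fold-changes follow the convention of treatment-effect reporting: an
"x-fold increase" of A over B is mean(A)/mean(B); an "x-fold decrease"
under treatment is (untreated mean)/(treated mean).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "fold_change",
    "anova_oneway",
    "anova_tukey",
    "kruskal_wallis",
    "kruskal_bky",
    "bky_two_stage",
    "pearson_corr",
    "linreg",
    "p_stars",
]

P_STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


def p_stars(p: float) -> str:
    """Significance stars at the conventional 0.05/0.01/0.001/0.0001 levels."""
    if math.isnan(p):
        return ""
    return "*" * sum(p <= t for t in P_STAR_THRESHOLDS)


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus test plus pairwise contrasts for one endpoint."""

    endpoint: str
    group_names: tuple[str, ...]
    n: tuple[int, ...]
    means: tuple[float, ...]
    sems: tuple[float, ...]
    test: str
    statistic: float
    pvalue: float
    contrasts: pd.DataFrame  # columns: group_a, group_b, p_raw, p_adj, fold_change

    def __post_init__(self) -> None:
        adj = self.contrasts["p_adj"].to_numpy(dtype=float)
        finite = adj[np.isfinite(adj)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValueError("adjusted p-values must lie in [0, 1]")

    def summary(self) -> str:
        lines = [f"{self.endpoint}: {self.test}  "
                 f"stat={self.statistic:.4g}  p={self.pvalue:.4g}"]
        for name, n, m, s in zip(self.group_names, self.n, self.means, self.sems):
            lines.append(f"  {name:<18} n={n:<3} mean={m:.4g} sem={s:.4g}")
        for _, row in self.contrasts.iterrows():
            lines.append(
                f"  {row.group_a} vs {row.group_b}: fold={row.fold_change:.3g} "
                f"p_adj={row.p_adj:.4g} {p_stars(row.p_adj)}")
        return "\n".join(lines)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation or simple linear regression between two variables."""

    x_name: str
    y_name: str
    method: str  # "pearson" | "linreg"
    n: int
    r: float = math.nan
    r2: float = math.nan
    slope: float = math.nan
    intercept: float = math.nan
    pvalue: float = math.nan

    def __post_init__(self) -> None:
        if not math.isnan(self.r) and not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r out of [-1, 1]")
        if not math.isnan(self.r2) and not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r^2 out of [0, 1]")

    def equation(self) -> str:
        return f"Y = {self.slope:.4g}*X + {self.intercept:.4g}"


def _clean_groups(groups) -> list[np.ndarray]:
    out = []
    for g in groups:
        a = np.asarray(g, dtype=float)
        a = a[np.isfinite(a)]
        out.append(a)
    return out


def fold_change(group_a, group_b) -> float:
    """Ratio of means mean(a)/mean(b)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    mb = float(np.nanmean(b))
    if mb == 0:
        raise ZeroDivisionError("reference group mean is zero")
    return float(np.nanmean(a)) / mb


def _group_stats(named_groups: dict[str, np.ndarray]):
    names = tuple(named_groups)
    n = tuple(int(g.size) for g in named_groups.values())
    means = tuple(float(g.mean()) if g.size else math.nan
                  for g in named_groups.values())
    sems = tuple(float(g.std(ddof=1) / math.sqrt(g.size)) if g.size > 1
                 else math.nan for g in named_groups.values())
    return names, n, means, sems


def _pairwise_folds(named_groups: dict[str, np.ndarray]) -> dict[tuple, float]:
    folds = {}
    for (na, ga), (nb, gb) in itertools.combinations(named_groups.items(), 2):
        try:
            folds[(na, nb)] = fold_change(ga, gb)
        except ZeroDivisionError:
            folds[(na, nb)] = math.nan
    return folds


def anova_oneway(groups) -> tuple[float, float]:
    """One-way ANOVA omnibus F statistic and p-value."""
    cleaned = _clean_groups(groups)
    if len(cleaned) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in cleaned):
        raise ValueError("every group needs n >= 2")
    f_stat, p = sps.f_oneway(*cleaned)
    if f_stat < 0.0:  # cancellation when between-group variance is ~0
        f_stat, p = 0.0, 1.0
    return float(f_stat), float(p)


def anova_tukey(named_groups: dict[str, "np.ndarray"],
                endpoint: str = "endpoint") -> GroupComparison:
    """One-way ANOVA with Tukey-HSD-adjusted pairwise contrasts.

    Adjusted p-values come from the studentized-range distribution via
    statsmodels' Tukey HSD implementation.
    """
    groups = dict(zip(named_groups, _clean_groups(named_groups.values())))
    f_stat, p = anova_oneway(groups.values())

    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([np.repeat(name, g.size)
                             for name, g in groups.items()])
    tk = pairwise_tukeyhsd(values, labels)
    folds = _pairwise_folds(groups)
    # statsmodels orders pairs as combinations of the sorted unique labels
    pairs = list(itertools.combinations(tk.groupsunique, 2))
    rows = []
    for (ga, gb), p_adj in zip(pairs, tk.pvalues):
        if (ga, gb) in folds:
            fold = folds[(ga, gb)]
        else:
            f = folds[(gb, ga)]
            fold = 1.0 / f if f not in (0.0, math.nan) and f == f else math.nan
        rows.append({"group_a": ga, "group_b": gb,
                     "p_raw": math.nan, "p_adj": float(p_adj),
                     "fold_change": fold})
    names, n, means, sems = _group_stats(groups)
    return GroupComparison(
        endpoint=endpoint, group_names=names, n=n, means=means, sems=sems,
        test="one-way ANOVA + Tukey HSD",
        statistic=float(f_stat), pvalue=float(p),
        contrasts=pd.DataFrame(rows),
    )


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with chi-square p-value.

    All-identical data yield H = 0, p = 1 rather than an error.
    """
    cleaned = _clean_groups(groups)
    if sum(g.size for g in cleaned) < 5:
        raise ValueError("need total n >= 5")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*cleaned)
    return float(h), float(p)


def bky_two_stage(pvalues, q: float = 0.05
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage linear step-up FDR procedure (BKY 2006, Definition 6).

    Stage 1 runs Benjamini-Hochberg at q' = q/(1+q) to estimate the
    number of true nulls m0 = m - r1; stage 2 reruns BH at q'*m/m0.
    No stage-1 rejection rejects nothing; r1 = m rejects everything.
    Returns (rejected boolean mask, adjusted p-values); the adjusted
    values are specific to ``q`` and satisfy (adjusted <= q) == rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    q1 = q / (1.0 + q)

    def bh(alpha: float) -> np.ndarray:
        order = np.argsort(p, kind="stable")
        thresh = alpha * (np.arange(1, m + 1)) / m
        below = p[order] <= thresh
        k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
        rej = np.zeros(m, dtype=bool)
        rej[order[:k]] = True
        return rej

    def bh_adjusted() -> np.ndarray:
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    r1 = int(bh(q1).sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool), np.ones(m)
    if r1 == m:
        return np.ones(m, dtype=bool), np.minimum(bh_adjusted() * (1.0 + q), 1.0)
    m0 = m - r1
    rejected = bh(q1 * m / m0)
    adjusted = np.minimum(bh_adjusted() * (1.0 + q) * m0 / m, 1.0)
    return rejected, adjusted


def kruskal_bky(named_groups: dict[str, "np.ndarray"],
                endpoint: str = "endpoint", q: float = 0.05
                ) -> GroupComparison:
    """Kruskal-Wallis omnibus + pairwise rank-sum tests, BKY-adjusted.

    Pairwise raw p-values come from two-sided Mann-Whitney U tests;
    the two-stage step-up procedure supplies the adjusted values.
    """
    groups = dict(zip(named_groups, _clean_groups(named_groups.values())))
    h, p = kruskal_wallis(groups.values())
    pairs = list(itertools.combinations(groups, 2))
    raw = []
    for ga, gb in pairs:
        a, b = groups[ga], groups[gb]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            raw.append(1.0)
        else:
            raw.append(float(sps.mannwhitneyu(a, b, alternative="two-sided")
                             .pvalue))
    _, adj = bky_two_stage(np.array(raw), q=q)
    folds = _pairwise_folds(groups)
    contrasts = pd.DataFrame([
        {"group_a": ga, "group_b": gb, "p_raw": pr, "p_adj": pa,
         "fold_change": folds[(ga, gb)]}
        for (ga, gb), pr, pa in zip(pairs, raw, adj)
    ])
    names, n, means, sems = _group_stats(groups)
    return GroupComparison(
        endpoint=endpoint, group_names=names, n=n, means=means, sems=sems,
        test="Kruskal-Wallis + BKY two-stage",
        statistic=h, pvalue=p, contrasts=contrasts,
    )


def pearson_corr(x, y, x_name: str = "x", y_name: str = "y"
                 ) -> CorrelationResult:
    """Pearson r with two-sided p (t transform); pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need n >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(x_name=x_name, y_name=y_name, method="pearson",
                             n=int(x.size), r=float(r), r2=float(r) ** 2,
                             pvalue=float(p))


def linreg(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Ordinary least squares y = slope*x + intercept with r^2 and slope p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need n >= 3 complete pairs")
    if np.all(x == x[0]):
        raise ValueError("constant x")
    res = sps.linregress(x, y)
    return CorrelationResult(
        x_name=x_name, y_name=y_name, method="linreg", n=int(x.size),
        r=float(res.rvalue), r2=float(res.rvalue) ** 2,
        slope=float(res.slope), intercept=float(res.intercept),
        pvalue=float(res.pvalue),
    )
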