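"""Comparison machinery for manual vs automated morphometry tables.

Branch-by-branch comparison joins two tables on the Raabe binary label and
summarises agreement per measure with a least-squares slope forced through
the origin plus the conventional (mean-centred) Pearson correlation.
Cross-strain comparisons use one-way ANOVA on per-cast generation means and
paired t tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchedPairs",
    "RegressionResult",
    "AnovaResult",
    "PairedTResult",
    "match_branches",
    "regression_through_origin",
    "anova_by_strain",
    "paired_t_bonferroni",
    "compare_tables",
    "fold_to_quadrant",
]

MEASURES = ["length_mm", "diameter_mm", "branch_angle_deg", "gravity_angle_deg"]


@dataclass
class MatchedPairs:
    """Inner join of two morphometry tables on the binary label."""

    pairs: pd.DataFrame           # index label; columns <measure>_a / <measure>_b
    only_a: list[str] = field(default_factory=list)
    only_b: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.pairs)

    def xy(self, measure: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.pairs[[f"{measure}_a", f"{measure}_b"]].dropna()
        return sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)


@dataclass
class RegressionResult:
    slope: float
    r: float
    r2_uncentered: float
    n: int
    flag: str | None = None


@dataclass
class AnovaResult:
    f: float
    p: float
    significant_05: bool
    significant_01: bool
    flag: str | None = None


@dataclass
class PairedTResult:
    t: float
    p: float
    p_adjusted: float
    n: int
    flag: str | None = None


def match_branches(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   measures: list[str] | None = None) -> MatchedPairs:
    """Pair corresponding branches: only labels present in both tables."""
    measures = measures or MEASURES
    for name, t in (("first", table_a), ("second", table_b)):
        if t["label"].duplicated().any():
            raise ValueError(f"duplicate labels in {name} table")
    a = table_a.set_index("label")
    b = table_b.set_index("label")
    shared = a.index.intersection(b.index)
    cols = {}
    for m in measures:
        if m in a.columns:
            cols[f"{m}_a"] = a.loc[shared, m]
        if m in b.columns:
            cols[f"{m}_b"] = b.loc[shared, m]
    return MatchedPairs(
        pairs=pd.DataFrame(cols, index=shared),
        only_a=sorted(a.index.difference(b.index)),
        only_b=sorted(b.index.difference(a.index)),
    )


def regression_through_origin(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Least-squares slope with the intercept forced through (0, 0).

    ``slope = sum(x*y) / sum(x^2)``; ``r`` is the ordinary mean-centred
    Pearson coefficient, reported alongside the uncentred R² of the
    through-origin fit (the two answer different questions, so both are
    emitted).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2:
        raise ValueError("need at least two points")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("all x are zero; through-origin slope undefined")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    syy = float(y @ y)
    r2u = 1.0 - float(resid @ resid) / syy if syy > 0 else np.nan
    flag = None
    if np.std(x) == 0 or np.std(y) == 0:
        r = np.nan
        flag = "zero_variance"
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return RegressionResult(slope=slope, r=r, r2_uncentered=r2u, n=len(x), flag=flag)


def anova_by_strain(groups: dict[str, np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA across strains.

    ``groups`` maps strain name to the per-cast generation means (casts are
    the replicates).  Degenerate inputs (all values identical) report F = 0,
    p = 1 with a flag.
    """
    arrays = [np.asarray(v, float) for v in groups.values()]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 strains with >= 2 casts each")
    allv = np.concatenate(arrays)
    if np.allclose(allv, allv[0]):
        return AnovaResult(0.0, 1.0, False, False, flag="degenerate")
    f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):  # identical within-group values, differing between
        return AnovaResult(np.inf, 0.0, True, True, flag="zero_within_variance")
    return AnovaResult(float(f), float(p), p < 0.05, p < 0.01)


def paired_t_bonferroni(comparisons: dict[str, tuple[np.ndarray, np.ndarray]],
                        m: int | None = None, alpha: float = 0.01,
                        ) -> tuple[dict[str, PairedTResult], float]:
    """Paired t tests with Bonferroni correction over ``m`` comparisons.

    Reports each raw p, the adjusted ``min(1, m*p)`` and the family
    threshold ``alpha / m``.  Zero-variance differences are flagged: t = 0
    (p = 1) when the samples are identical, and the p -> 0 limit when every
    difference equals the same non-zero constant.
    """
    m = m if m is not None else len(comparisons)
    if m < 1:
        raise ValueError("need at least one comparison")
    out: dict[str, PairedTResult] = {}
    for name, (a, b) in comparisons.items():
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if len(a) != len(b) or len(a) < 2:
            raise ValueError(f"comparison {name!r} needs >= 2 pairs")
        d = a - b
        if np.std(d, ddof=1) == 0.0:
            if np.allclose(d, 0.0):
                out[name] = PairedTResult(0.0, 1.0, 1.0, len(a), flag="degenerate")
            else:
                out[name] = PairedTResult(np.inf if d.mean() > 0 else -np.inf,
                                          0.0, 0.0, len(a), flag="zero_variance")
            continue
        res = stats.ttest_rel(a, b)
        p = float(res.pvalue)
        out[name] = PairedTResult(float(res.statistic), p, min(1.0, m * p), len(a))
    return out, alpha / m


def anova_table(tables_by_strain: dict[str, list[pd.DataFrame]],
                measures: list[str] | None = None) -> pd.DataFrame:
    """Per-generation, per-measure ANOVA across strains.

    ``tables_by_strain`` maps strain name to that strain's cast-level
    morphometry tables (one per cast).  Casts are the replicates: each
    cast contributes its per-generation mean of the measure.  Generations
    where fewer than two strains have two casts are skipped.
    """
    measures = measures or MEASURES
    means: dict[str, list[pd.DataFrame]] = {}
    for strain, tables in tables_by_strain.items():
        per_cast = []
        for t in tables:
            w = t.copy()
            w["generation"] = w["label"].str.len()
            per_cast.append(w.groupby("generation")[
                [m for m in measures if m in w.columns]].mean())
        means[strain] = per_cast
    all_gens = sorted({g for casts in means.values()
                       for c in casts for g in c.index})
    rows = []
    for gen in all_gens:
        for m in measures:
            groups = {}
            for strain, casts in means.items():
                vals = [c.loc[gen, m] for c in casts
                        if gen in c.index and m in c.columns
                        and np.isfinite(c.loc[gen, m])]
                if len(vals) >= 2:
                    groups[strain] = np.asarray(vals)
            if len(groups) < 2:
                continue
            res = anova_by_strain(groups)
            rows.append({"generation": gen, "measure": m, "f": res.f,
                         "p": res.p, "significant_05": res.significant_05,
                         "significant_01": res.significant_01,
                         "n_strains": len(groups)})
    return pd.DataFrame(rows)


def fold_to_quadrant(angles_deg: np.ndarray) -> np.ndarray:
    """Fold gravity angles from [0, 180] onto [0, 90] (manual convention)."""
    a = np.asarray(angles_deg, float)
    return np.where(a > 90.0, 180.0 - a, a)


def compare_tables(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   fold_gravity: bool = False) -> pd.DataFrame:
    """Through-origin slope and Pearson r per measure for two tables.

    Returns one row per measure with slope, r, uncentred R² and n.  With
    ``fold_gravity`` both tables' gravity angles are folded to [0, 90]
    before comparison.
    """
    a, b = table_a.copy(), table_b.copy()
    if fold_gravity:
        for t in (a, b):
            if "gravity_angle_deg" in t.columns:
                t["gravity_angle_deg"] = fold_to_quadrant(t["gravity_angle_deg"])
    matched = match_branches(a, b)
    rows = []
    for m in MEASURES:
        if f"{m}_a" not in matched.pairs.columns or f"{m}_b" not in matched.pairs.columns:
            continue
        x, y = matched.xy(m)
        if len(x) < 2:
            continue
        try:
            res = regression_through_origin(x, y)
        except ValueError:
            continue
        rows.append({"measure": m, "slope": res.slope, "r": res.r,
                     "r2_uncentered": res.r2_uncentered, "n": res.n})
    return pd.DataFrame(rows)
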