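"""Optimal-set selection: ANOVA, Tukey HSD homogeneous subsets, and the
minimal-cardinality rule.

For a fixed measurement-position set, the 15 feature sets are the levels of a
one-way layout whose observations are the per-repeat metric values (and
symmetrically for the 63 position sets at a fixed feature set). When the
one-way ANOVA is significant, Tukey HSD grouping partitions the levels into
homogeneous subsets — maximal runs of consecutively ordered level means whose
range is non-significant under the studentized-range test, using the
within-group mean square and degrees of freedom from the ANOVA and the
critical value for the total number of levels. The optimal level is then
the member of the best subset with the fewest positions/features, ties broken
by the better mean, then by canonical name.

Lower means are better for NRMS and NMAE; higher means are better for CC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .combinatorics import enumerate_fs, enumerate_mps

logger = logging.getLogger(__name__)

#: Metrics where a larger mean indicates better estimation.
HIGHER_IS_BETTER = {"cc"}

METRIC_NAMES = ("nrms", "nmae", "cc")


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    ms_within: float
    df_within: int
    n_levels: int


@dataclass
class SubsetGrouping:
    """Homogeneous-subset layout for one metric over one factor's levels."""

    metric: str
    level_means: dict[str, float]
    level_n: dict[str, int]
    subsets: list[list[str]]         # best subset first
    subset_p: list[float]            # within-subset range-test p (SPSS 'Sig.')
    anova_p: float
    significant: bool
    alpha: float

    @property
    def best_subset(self) -> list[str]:
        return self.subsets[0]

    def ordered_levels(self) -> list[str]:
        asc = self.metric not in HIGHER_IS_BETTER
        return sorted(
            self.level_means, key=lambda k: self.level_means[k], reverse=not asc
        )


@dataclass(frozen=True)
class OptimalSelection:
    metric: str
    optimal_level: str
    cardinality: int
    mean_metric: float
    significant: bool


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Fixed-effects one-way ANOVA from textbook sums of squares.

    Degenerate separation (zero within-group variance, distinct means) is
    reported as F = inf, p = 0; fully constant data as F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two levels")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"level {k!r} has fewer than 2 replicates")
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_between = len(arrays) - 1
    df_within = all_values.size - len(arrays)
    ms_within = ss_within / df_within
    if ss_within == 0:
        if ss_between == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_between) / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        ms_within=float(ms_within),
        df_within=int(df_within),
        n_levels=len(arrays),
    )


def two_way_anova(results: pd.DataFrame, value: str = "nrms") -> dict[str, dict[str, float]]:
    """Balanced two-factor ANOVA with interaction over (mps, fs, repeat).

    Requires the full factorial with an equal number of replicates per cell.
    Returns F and p for the position-set factor, the feature-set factor and
    their interaction.
    """
    counts = results.groupby(["mps", "fs"]).size()
    a = results["mps"].nunique()
    b = results["fs"].nunique()
    if len(counts) != a * b or counts.nunique() != 1:
        raise ValueError("design must be a full factorial with equal replicates")
    n = int(counts.iloc[0])
    if n < 2:
        raise ValueError("need at least 2 replicates per cell")

    y = results[value].to_numpy(dtype=float)
    grand = y.mean()
    mean_a = results.groupby("mps")[value].mean()
    mean_b = results.groupby("fs")[value].mean()
    mean_cell = results.groupby(["mps", "fs"])[value].mean()

    ss_a = b * n * ((mean_a - grand) ** 2).sum()
    ss_b = a * n * ((mean_b - grand) ** 2).sum()
    cell_effect = (
        mean_cell
        - mean_a.reindex(mean_cell.index.get_level_values(0)).to_numpy()
        - mean_b.reindex(mean_cell.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ab = n * (cell_effect**2).sum()
    resid = y - mean_cell.reindex(
        pd.MultiIndex.from_frame(results[["mps", "fs"]])
    ).to_numpy()
    ss_e = (resid**2).sum()

    df = {"mps": a - 1, "fs": b - 1, "interaction": (a - 1) * (b - 1)}
    df_e = a * b * (n - 1)
    ms_e = ss_e / df_e
    out = {}
    for name, ss in (("mps", ss_a), ("fs", ss_b), ("interaction", ss_ab)):
        if ms_e == 0:
            f_stat = 0.0 if ss == 0 else np.inf
            p = 1.0 if ss == 0 else 0.0
        else:
            f_stat = (ss / df[name]) / ms_e
            p = float(stats.f.sf(f_stat, df[name], df_e))
        out[name] = {"F": float(f_stat), "p": float(p), "df": df[name]}
    out["residual"] = {"df": df_e, "ms": float(ms_e)}
    return out


def _range_p(span: float, se: float, k: int, df: int) -> float:
    """p-value of the studentized range of a run of k ordered means."""
    if k < 2:
        return 1.0
    if se == 0:
        return 1.0 if span == 0 else 0.0
    return float(stats.studentized_range.sf(span / se, k, df))


def tukey_subsets(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    metric: str = "nrms",
) -> SubsetGrouping:
    """SPSS-style Tukey HSD homogeneous subsets.

    Levels are ordered best-first (ascending means for error metrics,
    descending for CC). A candidate run of consecutive levels is accepted when
    the studentized range of its extreme means, scaled by sqrt(MS_within/n_h),
    does not exceed the critical value q(alpha; k, df) for k = total number of
    levels; maximal accepted runs are the reported subsets. With equal
    replicate counts this coincides with grouping by mutual pairwise
    non-significance. The per-subset p ('Sig.') evaluates the subset's own
    range with the subset's size.
    """
    anova = one_way_anova(groups)
    ns = {k: np.asarray(v).size for k, v in groups.items()}
    if len(set(ns.values())) > 1:
        n_h = len(ns) / sum(1.0 / n for n in ns.values())
        logger.warning(
            "unbalanced replicates %s; using harmonic mean n = %.3f",
            dict(ns), n_h,
        )
    else:
        n_h = next(iter(ns.values()))
    se = float(np.sqrt(anova.ms_within / n_h))

    means = {k: float(np.mean(v)) for k, v in groups.items()}
    asc = metric not in HIGHER_IS_BETTER
    ordered = sorted(means, key=lambda k: means[k], reverse=not asc)
    mvals = np.array([means[k] for k in ordered])

    k_total = len(ordered)
    if se > 0:
        q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k_total, anova.df_within))
        def compatible(i: int, j: int) -> bool:
            return abs(mvals[j] - mvals[i]) / se <= q_crit
    else:
        def compatible(i: int, j: int) -> bool:  # zero noise: exact ties only
            return mvals[j] == mvals[i]

    subsets: list[list[str]] = []
    subset_p: list[float] = []
    prev_end = -1
    for i in range(k_total):
        j = i
        while j + 1 < k_total and compatible(i, j + 1):
            j += 1
        if j > prev_end or not subsets:  # maximal run, not nested in previous
            run = ordered[i : j + 1]
            subsets.append(run)
            subset_p.append(
                _range_p(abs(mvals[j] - mvals[i]), se, len(run), anova.df_within)
            )
            prev_end = j
        if j == k_total - 1:
            break

    return SubsetGrouping(
        metric=metric,
        level_means=means,
        level_n={k: int(v) for k, v in ns.items()},
        subsets=subsets,
        subset_p=subset_p,
        anova_p=anova.p_value,
        significant=bool(anova.p_value < alpha),
        alpha=alpha,
    )


def pick_optimum(grouping: SubsetGrouping, cardinality: dict[str, int]) -> OptimalSelection:
    """Minimal-cardinality member of the best subset, ties by better mean.

    Remaining ties fall back to canonical-name order (logged). When the ANOVA
    was not significant, the selection is still computed but flagged.
    """
    best = grouping.best_subset
    if not best:
        raise ValueError("best subset is empty")
    asc = grouping.metric not in HIGHER_IS_BETTER
    sign = 1.0 if asc else -1.0

    min_card = min(cardinality[lvl] for lvl in best)
    candidates = [lvl for lvl in best if cardinality[lvl] == min_card]
    best_mean = min(sign * grouping.level_means[lvl] for lvl in candidates)
    tied = sorted(
        lvl for lvl in candidates
        if sign * grouping.level_means[lvl] == best_mean
    )
    if len(tied) > 1:
        logger.info(
            "tie among %s for metric %s; choosing %s by name order",
            tied, grouping.metric, tied[0],
        )
    winner = tied[0]
    return OptimalSelection(
        metric=grouping.metric,
        optimal_level=winner,
        cardinality=min_card,
        mean_metric=grouping.level_means[winner],
        significant=grouping.significant,
    )


def _grouped_values(results: pd.DataFrame, fixed: str, fixed_value: str,
                    factor: str, metric: str) -> dict[str, np.ndarray]:
    sub = results[results[fixed] == fixed_value]
    return {
        lvl: g[metric].dropna().to_numpy()
        for lvl, g in sub.groupby(factor)
    }


def _level_cardinality(level: str, factor: str) -> int:
    return len(level.split("+")) if factor == "mps" else len(level)


def optimal_per_fixed(
    results: pd.DataFrame,
    fixed: str,
    factor: str,
    alpha: float = 0.05,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> pd.DataFrame:
    """Optimal ``factor`` level for every value of the ``fixed`` factor.

    ``fixed``/``factor`` are 'mps' and 'fs' in either order. Rows follow the
    deterministic enumeration order; one column per metric.
    """
    fixed_levels = _enumeration_order(results[fixed].unique(), fixed)
    rows = []
    for fv in fixed_levels:
        row: dict[str, object] = {fixed: fv}
        for metric in metrics:
            groups = _grouped_values(results, fixed, fv, factor, metric)
            groups = {k: v for k, v in groups.items() if v.size >= 2}
            if not groups:
                raise ValueError(
                    f"no {factor} level with replicates for {fixed}={fv}"
                )
            if len(groups) == 1:
                # a single available level is trivially optimal; no ANOVA
                (lvl, vals), = groups.items()
                row[metric] = lvl
                row[f"{metric}_mean"] = float(np.mean(vals))
                row[f"{metric}_anova_p"] = np.nan
                row[f"{metric}_significant"] = False
                continue
            grouping = tukey_subsets(groups, alpha=alpha, metric=metric)
            card = {lvl: _level_cardinality(lvl, factor) for lvl in groups}
            sel = pick_optimum(grouping, card)
            row[metric] = sel.optimal_level
            row[f"{metric}_mean"] = sel.mean_metric
            row[f"{metric}_anova_p"] = grouping.anova_p
            row[f"{metric}_significant"] = grouping.significant
        rows.append(row)
    return pd.DataFrame(rows)


def _enumeration_order(levels, factor: str) -> list[str]:
    levels = list(levels)
    if factor == "mps":
        channels = sorted({p for lvl in levels for p in lvl.split("+")})
        order = ["+".join(m) for m in enumerate_mps(tuple(channels))]
    else:
        letters = [f for f in "VIWZ" if any(f in lvl for lvl in levels)]
        order = ["".join(f) for f in enumerate_fs(tuple(letters))]
    rank = {name: i for i, name in enumerate(order)}
    return sorted(levels, key=lambda lvl: rank.get(lvl, len(rank)))


def build_reports(
    results: pd.DataFrame,
    alpha: float = 0.05,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(optimal FS per MPS, optimal MPS per FS) report tables."""
    fs_per_mps = optimal_per_fixed(results, "mps", "fs", alpha=alpha, metrics=metrics)
    mps_per_fs = optimal_per_fixed(results, "fs", "mps", alpha=alpha, metrics=metrics)
    return fs_per_mps, mps_per_fs
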