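"""Nonparametric dose-response statistics on region activation volumes,
plus the repeated-measures analysis of region time courses.

Region tables are long-format DataFrames with columns ``region_id``,
``subject_id``, ``group`` and ``value`` (a voxel count or other scalar).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .activation import FdrParams, fdr_filter

__all__ = [
    "kruskal_wallis_by_region",
    "wilcoxon_posthoc",
    "rank_sum_exact",
    "region_fdr_cutoff",
    "rm_anova_interaction",
    "sidak_alpha",
]

_TABLE_COLS = ("region_id", "subject_id", "group", "value")


def _check_table(table: pd.DataFrame) -> None:
    missing = set(_TABLE_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    per_subj = table.groupby("subject_id")["group"].nunique()
    if (per_subj > 1).any():
        bad = per_subj[per_subj > 1].index.tolist()
        raise ValueError(f"subjects assigned to multiple groups: {bad}")


def kruskal_wallis_by_region(
    table: pd.DataFrame,
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Kruskal-Wallis H across dose groups, per region, ranked by p.

    Output mirrors a dose-response summary table: one row per region with
    per-group medians, the tie-corrected H statistic and its chi-square
    p-value, sorted ascending by p (ties broken by region id).  Regions
    whose values are identical across all subjects get p = 1 by convention.
    """
    _check_table(table)
    groups = group_order or sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = table.groupby("group")["subject_id"].nunique()
    if (sizes.reindex(groups).fillna(0) < 2).any():
        raise ValueError("need at least two subjects per group")

    rows = []
    for rid, sub in table.groupby("region_id"):
        samples = [sub.loc[sub["group"] == g, "value"].to_numpy(float) for g in groups]
        values = np.concatenate(samples)
        if np.ptp(values) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        row = {"region_id": rid}
        for g, s in zip(groups, samples):
            row[f"med_{g}"] = float(np.median(s))
        row["H"] = float(h)
        row["p_value"] = float(p)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["p_value", "region_id"], kind="stable"
    ).reset_index(drop=True)
    return out


def rank_sum_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum p-value by exhaustive enumeration.

    Enumerates all C(n_a+n_b, n_a) assignments of the pooled (tied) ranks to
    group *a* and doubles the smaller tail of the observed rank sum (capped
    at 1), so ties are handled exactly.  Returns (rank_sum_a, p).
    Intended for min(n) <= 10; cost grows combinatorially beyond that.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    w_obs = ranks[:n_a].sum()
    n = n_a + n_b
    total = comb(n, n_a)
    le = ge = 0
    for idx in combinations(range(n), n_a):
        w = ranks[list(idx)].sum()
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return float(w_obs), float(p)


def _rank_sum_normal(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Normal-approximation rank-sum with tie and continuity correction.

    Returns (rank_sum_a, z, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n) * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(w), 0.0, 1.0
    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(w), float(z), float(min(1.0, p))


def wilcoxon_posthoc(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Per-region two-sided rank-sum contrast between two groups.

    Uses the exact enumeration whenever min(n_a, n_b) <= ``exact_max_n``
    (typical dose-group sizes), otherwise the tie-corrected normal
    approximation with continuity correction.  Reports group medians, a
    direction symbol ('<', '>' or '='), the normal-scale z, and the
    variance-explained effect size omega^2 = (z^2 - 1) / N (reported
    alongside z; it can be slightly negative for near-null contrasts).
    Rows are sorted ascending by p with stable region-id tie-breaking.
    """
    _check_table(table)
    present = set(table["group"].unique())
    for g in (group_a, group_b):
        if g not in present:
            raise ValueError(f"group {g!r} not present in the table")
    rows = []
    for rid, sub in table.groupby("region_id"):
        a = sub.loc[sub["group"] == group_a, "value"].to_numpy(float)
        b = sub.loc[sub["group"] == group_b, "value"].to_numpy(float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"region {rid}: empty group")
        n = len(a) + len(b)
        _, z, _ = _rank_sum_normal(a, b)
        if np.ptp(np.concatenate([a, b])) == 0:
            w, p, z = float(stats.rankdata(np.concatenate([a, b]))[: len(a)].sum()), 1.0, 0.0
        elif min(len(a), len(b)) <= exact_max_n:
            w, p = rank_sum_exact(a, b)
        else:
            w, z, p = _rank_sum_normal(a, b)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        direction = "<" if med_a < med_b else (">" if med_a > med_b else "=")
        rows.append({
            "region_id": rid,
            f"med_{group_a}": med_a,
            "direction": direction,
            f"med_{group_b}": med_b,
            "p_value": float(p),
            "z": float(z),
            "omega_sq": float((z**2 - 1.0) / n),
        })
    return pd.DataFrame(rows).sort_values(
        ["p_value", "region_id"], kind="stable"
    ).reset_index(drop=True)


def region_fdr_cutoff(
    p_values: np.ndarray,
    q: float = 0.05,
    c_v: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Step-up filter across regions; returns (boundary p, keep-mask).

    The boundary is the largest p-value among kept regions (NaN when nothing
    is kept) — the across-region analogue of the voxelwise filter.
    """
    p = np.asarray(p_values, dtype=float)
    keep = fdr_filter(p, FdrParams(q=q, c_v=c_v))
    boundary = float(p[keep].max()) if keep.any() else float("nan")
    return boundary, keep


def sidak_alpha(m: int, family_alpha: float = 0.05) -> float:
    """Per-test alpha for m comparisons at a family-wise level: 1-(1-a)^(1/m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - family_alpha) ** (1.0 / m)


def rm_anova_interaction(
    time_courses: dict[str, np.ndarray],
    family_alpha: float = 0.05,
    compare_from: int = 0,
) -> dict:
    """Two-way mixed-design ANOVA: group (between) x time (repeated within).

    ``time_courses`` maps group label -> (subjects x acquisitions) array on
    a common acquisition grid.  Returns the classical decomposition with the
    interaction F tested against the within-subject error term
    (time x subject-within-group), plus per-timepoint two-sample Welch
    contrasts (two groups only) at the Sidak-adjusted per-test alpha over
    the ``compare_from:`` timepoint family.
    """
    groups = list(time_courses)
    mats = [np.atleast_2d(np.asarray(time_courses[g], dtype=float)) for g in groups]
    n_time = mats[0].shape[1]
    if n_time < 2:
        raise ValueError("need at least two timepoints")
    if any(m.shape[1] != n_time for m in mats):
        raise ValueError("all groups must share the acquisition grid")
    if any(m.shape[0] < 2 for m in mats):
        raise ValueError("need at least two subjects per group")

    all_data = np.concatenate(mats, axis=0)  # (N, T)
    n_g = np.array([m.shape[0] for m in mats])
    N = int(n_g.sum())
    T = n_time
    grand = all_data.mean()

    group_means = np.array([m.mean() for m in mats])
    subj_means = all_data.mean(axis=1)  # (N,)
    time_means = all_data.mean(axis=0)  # (T,), weighted by subjects
    cell_means = np.stack([m.mean(axis=0) for m in mats])  # (G, T)

    ss_group = T * float(np.sum(n_g * (group_means - grand) ** 2))
    group_of_subj = np.repeat(group_means, n_g)
    ss_subj = T * float(np.sum((subj_means - group_of_subj) ** 2))
    ss_time = N * float(np.sum((time_means - grand) ** 2))
    ss_cells = float(np.sum(n_g[:, None] * (cell_means - grand) ** 2))
    ss_inter = ss_cells - ss_group - ss_time
    ss_total = float(np.sum((all_data - grand) ** 2))
    ss_error = ss_total - ss_group - ss_subj - ss_time - ss_inter

    g = len(groups)
    df_inter = (g - 1) * (T - 1)
    df_error = (N - g) * (T - 1)
    ms_inter = ss_inter / df_inter
    ms_error = ss_error / df_error
    f_inter = ms_inter / ms_error
    p_inter = float(stats.f.sf(f_inter, df_inter, df_error))

    result = {
        "groups": groups,
        "F_interaction": float(f_inter),
        "df_interaction": (df_inter, df_error),
        "p_interaction": p_inter,
        "ss": {
            "group": ss_group, "subjects_within": ss_subj, "time": ss_time,
            "interaction": ss_inter, "error": ss_error, "total": ss_total,
        },
    }

    if g == 2:
        family = np.arange(compare_from, T)
        alpha = sidak_alpha(len(family), family_alpha)
        tt = stats.ttest_ind(mats[0][:, family], mats[1][:, family], axis=0, equal_var=False)
        result["per_timepoint"] = pd.DataFrame({
            "acquisition": family,
            "t": tt.statistic,
            "p_value": tt.pvalue,
            "significant": tt.pvalue < alpha,
        })
        result["sidak_alpha"] = alpha
    return result
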