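"""Connectedness-rating statistics.

Ratings are integers 0-5 (0 = nonanswer, excluded from all averages),
collected per participant and run for each of the four conditions plus a
pre-experiment baseline.  The omnibus condition effect is assessed with a
Kruskal-Wallis test on per-participant condition means (rank-based, robust
to the heteroscedasticity typical of bounded rating scales), followed by
Games-Howell post hoc comparisons (Welch-Satterthwaite df, studentized-range
p-values) and confirmatory Bonferroni-corrected pairwise t-tests.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "validate_ratings",
    "participant_condition_means",
    "condition_means",
    "kruskal_wallis",
    "games_howell",
    "bonferroni_pairwise_t",
]

REQUIRED_COLUMNS = ("participant", "condition", "rating")


def validate_ratings(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"ratings table is missing column {col!r}")
    r = table["rating"]
    if ((r < 0) | (r > 5)).any():
        raise ValueError("ratings must be integers in [0, 5]")


def participant_condition_means(
    table: pd.DataFrame, include_retroactive: bool = True
) -> pd.DataFrame:
    """Per-participant mean rating per condition, nonanswers (0) excluded.

    Baseline rows flagged retroactive are included by default; pass
    ``include_retroactive=False`` to drop them.
    """
    validate_ratings(table)
    t = table[table["rating"] > 0]
    if not include_retroactive and "retroactive_flag" in t.columns:
        t = t[~t["retroactive_flag"].astype(bool)]
    return (
        t.groupby(["condition", "participant"])["rating"].mean().rename("mean_rating")
        .reset_index()
    )


def condition_means(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-condition mean +/- SE over participant means, with flags for
    empty conditions and single-observation conditions (SE undefined)."""
    pm = participant_condition_means(table, **kwargs)
    rows = []
    for cond in table["condition"].unique():
        vals = pm.loc[pm["condition"] == cond, "mean_rating"].to_numpy()
        if len(vals) == 0:
            rows.append({"condition": cond, "mean": math.nan, "se": math.nan,
                         "n": 0, "flag": "empty"})
        elif len(vals) == 1:
            rows.append({"condition": cond, "mean": float(vals[0]), "se": math.nan,
                         "n": 1, "flag": "single-observation"})
        else:
            rows.append({"condition": cond, "mean": float(vals.mean()),
                         "se": float(vals.std(ddof=1) / math.sqrt(len(vals))),
                         "n": len(vals), "flag": ""})
    return pd.DataFrame(rows).sort_values("mean", ascending=False).reset_index(drop=True)


def _groups(table: pd.DataFrame, **kwargs) -> dict[str, np.ndarray]:
    pm = participant_condition_means(table, **kwargs)
    return {
        cond: grp["mean_rating"].to_numpy()
        for cond, grp in pm.groupby("condition")
        if len(grp) > 0
    }


def kruskal_wallis(table: pd.DataFrame, **kwargs) -> tuple[float, int, float]:
    """Kruskal-Wallis H (tie-corrected) over condition groups of
    per-participant mean ratings; df = groups - 1, chi-square p."""
    groups = _groups(table, **kwargs)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with valid ratings")
    vals = list(groups.values())
    df = len(vals) - 1
    flat = np.concatenate(vals)
    if np.all(flat == flat[0]):
        return 0.0, df, 1.0
    h, p = _stats.kruskal(*vals)
    return float(h), df, float(p)


def games_howell(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Games-Howell pairwise comparisons.

    Per pair: Welch-Satterthwaite df, studentized-range statistic
    q = |mean difference| / sqrt((s1^2/n1 + s2^2/n2) / 2), and the p-value
    from the studentized-range distribution with k groups (evaluated by
    numerical integration of its distribution function via scipy's
    ``studentized_range``).
    """
    groups = _groups(table, **kwargs)
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for cond, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {cond!r} has fewer than 2 observations")
    rows = []
    for (ca, a), (cb, b) in itertools.combinations(groups.items(), 2):
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        diff = a.mean() - b.mean()
        se2 = va / na + vb / nb
        if se2 == 0:
            rows.append({"group_a": ca, "group_b": cb, "mean_diff": float(diff),
                         "df": math.nan, "q": math.nan, "p": math.nan,
                         "flag": "zero-variance"})
            continue
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        q = abs(diff) / math.sqrt(se2 / 2.0)
        p = float(_stats.studentized_range.sf(q, k, df))
        rows.append({"group_a": ca, "group_b": cb, "mean_diff": float(diff),
                     "df": float(df), "q": float(q), "p": min(1.0, p), "flag": ""})
    return pd.DataFrame(rows)


def bonferroni_pairwise_t(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Pooled-variance pairwise t-tests with Bonferroni correction:
    adjusted p = min(1, raw p x number of pairs)."""
    groups = _groups(table, **kwargs)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for (ca, a), (cb, b) in itertools.combinations(groups.items(), 2):
        if len(a) < 2 or len(b) < 2:
            rows.append({"group_a": ca, "group_b": cb, "t": math.nan,
                         "p_raw": math.nan, "p_adj": math.nan, "flag": "too-few"})
            continue
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            rows.append({"group_a": ca, "group_b": cb, "t": 0.0,
                         "p_raw": 1.0, "p_adj": 1.0, "flag": "degenerate"})
            continue
        t, p = _stats.ttest_ind(a, b, equal_var=True)
        rows.append({"group_a": ca, "group_b": cb, "t": float(t),
                     "p_raw": float(p), "p_adj": min(1.0, float(p) * n_pairs),
                     "flag": ""})
    return pd.DataFrame(rows)
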