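"""Group comparisons for injury cohorts.

Covers the statistical backbone of sparing-versus-recovery analyses:
splitting animals into high-performing and impaired groups by locomotor
score, screening every brain region for group differences in spared
neurons under a Bonferroni-adjusted threshold, one-/two-way ANOVA with
Sidak-adjusted pairwise comparisons, and per-region rank correlation
between sparing and behavior.

Two-sample comparisons are Welch t-tests (groups are small and usually
unequal); Bonferroni control is applied as a threshold adjustment
(alpha / m over the m regions actually tested) rather than p-value
inflation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import SparingTable

__all__ = [
    "GroupComparison",
    "AnovaResult",
    "screen_regions",
    "split_by_bms",
    "anova_posthoc",
    "sparing_bms_association",
]

HIGH = "high"
IMPAIRED = "impaired"
EXCLUDED = "excluded"


@dataclass
class GroupComparison:
    """Per-region screening result under Bonferroni threshold control.

    ``table`` has one row per region tested (plus skipped rows flagged);
    ``m`` counts only regions actually tested, and the significance flag
    is ``p < alpha / m``.  ``gap`` is min(high) - max(impaired): positive
    when the worst high-performing animal still exceeds the best impaired
    one, the non-overlap signature of a recovery-relevant region.
    """

    table: pd.DataFrame
    m: int
    alpha: float

    @property
    def adjusted_threshold(self) -> float:
        return self.alpha / self.m if self.m else np.nan

    @property
    def significant_regions(self) -> list:
        t = self.table
        return sorted(t.loc[t["significant"] == True, "region"].tolist())  # noqa: E712


def _values_frame(values) -> pd.DataFrame:
    """Normalize input to columns (animal, region, value)."""
    if isinstance(values, SparingTable):
        df = values.per_animal_region
        df = df[~df["excluded"]][["animal", "region", "count"]].rename(
            columns={"count": "value"}
        )
        return df
    df = pd.DataFrame(values)
    if "value" not in df.columns:
        for cand in ("count", "sparing_pct"):
            if cand in df.columns:
                df = df.rename(columns={cand: "value"})
                break
    missing = {"animal", "region", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"values table missing columns {sorted(missing)}")
    return df[["animal", "region", "value"]]


def screen_regions(values, groups, alpha: float = 0.05) -> GroupComparison:
    """Screen every region for high-vs-impaired differences in sparing.

    Parameters
    ----------
    values
        A :class:`~supraconnect.metrics.SparingTable` (spared counts per
        animal and region, exclusions honored) or a long DataFrame with
        columns ``animal, region, value``.
    groups
        Mapping from animal id to ``'high'`` / ``'impaired'`` (other
        labels and missing animals are ignored), e.g. the output of
        :func:`split_by_bms` keyed by animal.
    alpha
        Family-wise error target; the per-region threshold is
        ``alpha / m`` with ``m`` the number of regions tested.

    Each region is compared with a Welch two-sample t-test; regions where
    either group has fewer than 2 animals are skipped with a flag.  The
    result is invariant to region and animal ordering.
    """
    df = _values_frame(values)
    if isinstance(groups, pd.DataFrame):
        groups = dict(zip(groups["animal_id"], groups["group"]))
    df = df[df["animal"].map(groups).isin([HIGH, IMPAIRED])].copy()
    df["group"] = df["animal"].map(groups)

    rows = []
    for region in sorted(df["region"].unique(), key=str):
        sub = df[df["region"] == region]
        hi = sub.loc[sub["group"] == HIGH, "value"].to_numpy(dtype=float)
        lo = sub.loc[sub["group"] == IMPAIRED, "value"].to_numpy(dtype=float)
        row = {
            "region": region,
            "n_high": len(hi),
            "n_impaired": len(lo),
            "mean_high": float(np.mean(hi)) if len(hi) else np.nan,
            "mean_impaired": float(np.mean(lo)) if len(lo) else np.nan,
        }
        if len(hi) < 2 or len(lo) < 2:
            row.update(
                mean_diff=np.nan, t_stat=np.nan, p_value=np.nan, gap=np.nan,
                skipped=True, significant=False,
            )
        else:
            t, p = sps.ttest_ind(hi, lo, equal_var=False)
            row.update(
                mean_diff=row["mean_high"] - row["mean_impaired"],
                t_stat=float(t),
                p_value=float(p),
                gap=float(np.min(hi) - np.max(lo)),
                skipped=False,
                significant=False,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    tested = ~table["skipped"]
    m = int(tested.sum())
    if m == 0:
        raise ValueError("no region had >= 2 animals per group; nothing to test")
    threshold = alpha / m
    table.loc[tested, "significant"] = table.loc[tested, "p_value"] < threshold
    return GroupComparison(table=table, m=m, alpha=alpha)


def split_by_bms(
    metadata: pd.DataFrame,
    high_threshold: float = 5.0,
    impaired_threshold: float = 3.5,
    score_col: str = "bms",
) -> pd.DataFrame:
    """Partition animals by final locomotor score.

    Scores at or above ``high_threshold`` (consistent plantar stepping)
    are ``'high'``, at or below ``impaired_threshold`` (no or infrequent
    stepping) ``'impaired'``, and scores in the open gap between the
    thresholds are ``'excluded'``.  Scores must lie within the 0-9 scale.
    """
    meta = pd.DataFrame(metadata)
    if "animal_id" not in meta.columns:
        raise ValueError("metadata must carry an animal_id column")
    scores = meta[score_col].to_numpy(dtype=float)
    if len(scores) and (np.min(scores) < 0 or np.max(scores) > 9):
        bad = meta.loc[(scores < 0) | (scores > 9), "animal_id"].tolist()
        raise ValueError(f"BMS scores outside [0, 9] for animals {bad}")
    group = np.full(len(scores), EXCLUDED, dtype=object)
    group[scores >= high_threshold] = HIGH
    group[scores <= impaired_threshold] = IMPAIRED
    out = meta[["animal_id", score_col]].copy()
    out["group"] = group
    return out


# ---------------------------------------------------------------------------
# ANOVA with Sidak post-hoc
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    anova_table: pd.DataFrame
    posthoc: pd.DataFrame
    degenerate: bool = False


def _sidak(p: float, k: int) -> float:
    return float(1.0 - (1.0 - p) ** k)


def anova_posthoc(
    data: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "condition",
    region_col: str = "region",
    design: str = "one-way",
) -> AnovaResult:
    """One- or two-way ANOVA with Sidak-adjusted pairwise comparisons.

    One-way: groups along ``group_col``.  Two-way: cell means over
    ``region_col`` x ``group_col`` with interaction; pairwise group
    comparisons are then made within each region level.  Pairwise t
    statistics use the pooled residual mean square, so in the two-group
    one-way case the ANOVA F equals the squared pairwise t exactly.
    Sidak adjustment: ``p_adj = 1 - (1 - p)^k`` over the k comparisons.

    Zero residual variance (all values identical within cells) flags the
    result degenerate with NaN statistics rather than failing.
    """
    df = pd.DataFrame(data).dropna(subset=[value_col])
    if design == "one-way":
        return _oneway(df, value_col, group_col)
    if design == "two-way":
        return _twoway(df, value_col, group_col, region_col)
    raise ValueError("design must be 'one-way' or 'two-way'")


def _oneway(df: pd.DataFrame, value_col: str, group_col: str) -> AnovaResult:
    groups = {g: s[value_col].to_numpy(dtype=float) for g, s in df.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("one-way design needs >= 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    y = df[value_col].to_numpy(dtype=float)
    n, k = len(y), len(groups)
    grand = y.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n - k
    mse = ss_within / df_w
    degenerate = mse <= 0
    f_stat = np.nan if degenerate else (ss_between / df_b) / mse
    p = np.nan if degenerate else float(sps.f.sf(f_stat, df_b, df_w))
    anova_table = pd.DataFrame(
        {
            "source": ["between", "within"],
            "ss": [ss_between, ss_within],
            "df": [df_b, df_w],
            "F": [f_stat, np.nan],
            "p": [p, np.nan],
        }
    )
    names = sorted(groups, key=str)
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        va, vb = groups[a], groups[b]
        if degenerate:
            t = pp = np.nan
        else:
            se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
            t = (va.mean() - vb.mean()) / se
            pp = float(2 * sps.t.sf(abs(t), df_w))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": va.mean() - vb.mean(),
                "t_stat": t,
                "p_raw": pp,
                "p_sidak": np.nan if degenerate else _sidak(pp, len(pairs)),
            }
        )
    return AnovaResult(
        anova_table=anova_table, posthoc=pd.DataFrame(rows), degenerate=degenerate
    )


def _twoway(
    df: pd.DataFrame, value_col: str, group_col: str, region_col: str
) -> AnovaResult:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    cell_sizes = df.groupby([region_col, group_col])[value_col].size()
    small = cell_sizes[cell_sizes < 2]
    if len(small):
        cell = small.index[0]
        raise ValueError(
            f"two-way design cell {cell} has n = {int(small.iloc[0])} < 2"
        )
    work = df.rename(
        columns={value_col: "_y", group_col: "_g", region_col: "_r"}
    )
    model = ols("_y ~ C(_r) * C(_g)", data=work).fit()
    mse = model.mse_resid
    degenerate = mse <= 0 or not np.isfinite(mse)
    if degenerate:
        anova_table = pd.DataFrame(
            {"source": ["C(_r)", "C(_g)", "interaction", "residual"], "F": np.nan, "p": np.nan}
        )
    else:
        aov = sm.stats.anova_lm(model, typ=2)
        anova_table = aov.reset_index().rename(
            columns={"index": "source", "PR(>F)": "p"}
        )
    df_resid = int(model.df_resid)
    regions = sorted(work["_r"].unique(), key=str)
    conds = sorted(work["_g"].unique(), key=str)
    pairs = list(itertools.combinations(conds, 2))
    k = len(regions) * len(pairs)
    rows = []
    for region in regions:
        sub = work[work["_r"] == region]
        for a, b in pairs:
            va = sub.loc[sub["_g"] == a, "_y"].to_numpy(dtype=float)
            vb = sub.loc[sub["_g"] == b, "_y"].to_numpy(dtype=float)
            if degenerate:
                t = pp = padj = np.nan
            else:
                se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
                t = (va.mean() - vb.mean()) / se
                pp = float(2 * sps.t.sf(abs(t), df_resid))
                padj = _sidak(pp, k)
            rows.append(
                {
                    "region": region,
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": va.mean() - vb.mean(),
                    "t_stat": t,
                    "p_raw": pp,
                    "p_sidak": padj,
                }
            )
    return AnovaResult(
        anova_table=anova_table, posthoc=pd.DataFrame(rows), degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# Sparing-behavior association
# ---------------------------------------------------------------------------


def sparing_bms_association(values, bms_scores) -> pd.DataFrame:
    """Per-region Spearman correlation between sparing and locomotor score.

    Parameters
    ----------
    values
        :class:`~supraconnect.metrics.SparingTable` or long DataFrame
        with ``animal, region, value``.
    bms_scores
        Mapping from animal id to final score, or a metadata DataFrame
        with ``animal_id`` and ``bms`` columns.

    Returns a table with rho, p, n, an undefined flag for constant
    vectors, and the underlying scatter points serialized in
    ``result.attrs['scatter']`` for plotting or CSV export.
    """
    df = _values_frame(values)
    if isinstance(bms_scores, pd.DataFrame):
        bms_scores = dict(zip(bms_scores["animal_id"], bms_scores["bms"]))
    df = df[df["animal"].isin(bms_scores)].copy()
    df["bms"] = df["animal"].map(bms_scores).astype(float)
    if df["animal"].nunique() < 3:
        raise ValueError("association requires >= 3 animals")

    rows = []
    for region in sorted(df["region"].unique(), key=str):
        sub = df[df["region"] == region]
        x = sub["value"].to_numpy(dtype=float)
        y = sub["bms"].to_numpy(dtype=float)
        if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
            rows.append(
                {"region": region, "rho": np.nan, "p_value": np.nan, "n": len(x), "undefined": True}
            )
        else:
            rho, p = sps.spearmanr(x, y)
            rows.append(
                {"region": region, "rho": float(rho), "p_value": float(p), "n": len(x), "undefined": False}
            )
    out = pd.DataFrame(rows)
    out.attrs["scatter"] = df[["animal", "region", "value", "bms"]].reset_index(drop=True)
    return out
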