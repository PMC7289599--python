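"""CpG-dyad methylation aggregation and group comparison.

A CpG dyad is the pair of complementary CG dinucleotides: the plus-strand
C at position ``i`` and the minus-strand C at ``i + 1``. Bisulfite calls
from the two strands are summed into one dyad record keyed by the
plus-strand C coordinate (0-based). Dyads covered at >= ``min_coverage``
in both conditions are compared per TE group with a paired t-test on
per-dyad methylation levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalIndex

CALL_COLUMNS = ["chrom", "pos", "strand", "coverage", "methylated"]


def aggregate_dyads(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge per-cytosine calls into CpG dyads.

    ``calls`` columns: chrom, pos (0-based C position), strand (+/-),
    coverage, methylated. A minus-strand C at ``i`` belongs to the dyad at
    ``i - 1``. Zero-coverage cytosines contribute nothing; a dyad covered
    on one strand only is kept with that strand's counts.

    Raises
    ------
    ValueError
        On duplicate (chrom, pos, strand) rows.
    """
    for col in CALL_COLUMNS:
        if col not in calls.columns:
            raise ValueError(f"calls missing column {col!r}")
    if calls.duplicated(subset=["chrom", "pos", "strand"]).any():
        raise ValueError("duplicate cytosine positions in input")
    if (calls["methylated"] > calls["coverage"]).any():
        raise ValueError("methylated count exceeds coverage")
    calls = calls[calls["coverage"] > 0]
    dyad_pos = np.where(calls["strand"] == "-", calls["pos"] - 1, calls["pos"])
    agg = (
        calls.assign(dyad_pos=dyad_pos)
        .groupby(["chrom", "dyad_pos"], sort=True)
        .agg(coverage=("coverage", "sum"), methylated=("methylated", "sum"))
        .reset_index()
        .rename(columns={"dyad_pos": "pos"})
    )
    agg["level"] = agg["methylated"] / agg["coverage"]
    return agg


def assign_groups(dyads: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Label each dyad with the group (TE family / region label) of the
    first region containing it; dyads outside every region get NaN.
    ``regions`` columns: chrom, start, end, group."""
    idx = IntervalIndex(regions.reset_index(drop=True))
    reg = regions.reset_index(drop=True)
    labels = []
    for r in dyads.itertuples():
        hits = idx.query(r.chrom, r.pos, r.pos + 1)
        labels.append(reg.at[min(hits), "group"] if hits else np.nan)
    return pd.Series(labels, index=dyads.index, name="group")


def compare_methylation(
    dyads_wt: pd.DataFrame,
    dyads_ko: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    min_coverage: int = 10,
) -> pd.DataFrame:
    """Per-group WT vs KO methylation with a paired t-test over dyads.

    Dyads are matched by (chrom, pos) across conditions; only dyads with
    coverage >= ``min_coverage`` in BOTH samples are retained. Groups come
    from ``regions`` (chrom/start/end/group) when given, else from a
    ``group`` column already on the WT dyad table, else all dyads form one
    group. The p-value is NaN (undefined) for groups with < 2 retained
    dyads or zero variance of the paired differences.

    Returns: group, n_dyads, mean_wt, mean_ko, delta (WT - KO), p_value.
    """
    merged = dyads_wt.merge(
        dyads_ko, on=["chrom", "pos"], suffixes=("_wt", "_ko"), how="inner"
    )
    merged = merged[
        (merged["coverage_wt"] >= min_coverage)
        & (merged["coverage_ko"] >= min_coverage)
    ].reset_index(drop=True)
    if regions is not None:
        merged["group"] = assign_groups(merged, regions).to_numpy()
    elif "group_wt" in merged.columns:
        merged["group"] = merged["group_wt"]
    elif "group" not in merged.columns:
        merged["group"] = "all"
    rows = []
    for group, sub in merged.dropna(subset=["group"]).groupby("group", sort=True):
        diffs = sub["level_wt"].to_numpy() - sub["level_ko"].to_numpy()
        if len(diffs) < 2 or np.allclose(diffs.var(ddof=0), 0):
            p = np.nan
        else:
            p = float(stats.ttest_rel(sub["level_wt"], sub["level_ko"]).pvalue)
        rows.append(
            dict(
                group=group,
                n_dyads=len(sub),
                mean_wt=float(sub["level_wt"].mean()),
                mean_ko=float(sub["level_ko"].mean()),
                delta=float(diffs.mean()),
                p_value=p,
            )
        )
    return pd.DataFrame(
        rows, columns=["group", "n_dyads", "mean_wt", "mean_ko", "delta", "p_value"]
    )
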