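"""TE-level read counting, filtering, and an approximate differential test.

Counting: a read overlapping (>= 1 bp) any fragment of an insertion
increments that insertion once, even when it spans two fragments with the
same insertion ID. Filtering drops insertions with fewer than 20 (two
biological replicates) or 30 (three replicates) reads summed across all
samples, plus insertions inside an excluded region (e.g. a deleted gene
cluster).

The differential stage is a deliberately simple engine — median-of-ratios
size factors, method-of-moments negative-binomial dispersion and a Wald
test on log fold change. It is NOT equivalent to a shrinkage-based NB GLM;
``differential_te`` also accepts a precomputed external results table for
users who fit the model elsewhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import RepeatAnnotation
from .intervals import GenomicInterval, IntervalIndex

MIN_TOTAL = {2: 20, 3: 30}


def count_reads_per_te(
    reads: pd.DataFrame,
    annotation: RepeatAnnotation,
    granularity: str = "insertion",
) -> pd.DataFrame:
    """Count reads per TE insertion (or per family).

    Parameters
    ----------
    reads : DataFrame
        sample_id, chrom, start, end — one aligned location per read.
    annotation : RepeatAnnotation
        Must carry ``insertion_id`` (fragments of one element share it).
    granularity : str
        ``insertion`` (rows keyed by insertion_id) or ``family``.

    Returns
    -------
    DataFrame
        Wide count table, rows = insertion_id (or family), columns =
        samples; integer counts, a read counted at most once per row key.
    """
    if "insertion_id" not in annotation.df.columns:
        raise ValueError("annotation lacks insertion_id")
    if granularity not in ("insertion", "family"):
        raise ValueError(f"unknown granularity {granularity!r}")
    keycol = "insertion_id" if granularity == "insertion" else "family"
    idx = annotation.index()
    ann = annotation.df
    samples = sorted(reads["sample_id"].unique())
    keys = sorted(ann[keycol].unique())
    table = pd.DataFrame(0, index=pd.Index(keys, name=keycol), columns=samples)
    for r in reads.itertuples():
        hit_keys = {ann.at[j, keycol] for j in idx.query(r.chrom, r.start, r.end)}
        for k in hit_keys:
            table.at[k, r.sample_id] += 1
    return table


def filter_te_counts(
    table: pd.DataFrame,
    n_replicates: int,
    excluded_region: GenomicInterval | None = None,
    annotation: RepeatAnnotation | None = None,
) -> pd.DataFrame:
    """Apply the minimum-total and excluded-region filters.

    Rows with total reads across all samples below 20 (``n_replicates=2``)
    or 30 (``n_replicates=3``) are dropped; rows whose insertion span
    overlaps ``excluded_region`` are dropped (requires ``annotation`` to
    locate insertions).
    """
    if n_replicates not in MIN_TOTAL:
        raise ValueError(
            f"unsupported design: {n_replicates} replicates (need 2 or 3)"
        )
    out = table[table.sum(axis=1) >= MIN_TOTAL[n_replicates]]
    if excluded_region is not None:
        if annotation is None:
            raise ValueError("excluded_region given without annotation")
        spans = annotation.element_spans().set_index("insertion_id")
        drop = []
        for key in out.index:
            if key in spans.index:
                row = spans.loc[key]
                iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
                if iv.overlap(excluded_region) > 0:
                    drop.append(key)
        out = out.drop(index=drop)
    return out.copy()


def size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (rows with any zero are excluded from
    the geometric reference)."""
    counts = table.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        return pd.Series(1.0, index=table.columns)
    logc = np.log(counts[positive])
    ref = logc.mean(axis=1)
    sf = np.exp(np.median(logc - ref[:, None], axis=0))
    return pd.Series(sf, index=table.columns)


def differential_te(
    table: pd.DataFrame,
    design: dict,
    alpha: float = 0.05,
    external_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-TE differential abundance between two groups.

    Parameters
    ----------
    table : DataFrame
        Filtered count table (rows TEs, columns samples).
    design : dict
        sample -> group label; exactly two groups, each with >= 2
        replicates. Fold changes are reported as group2 over group1 with
        groups in sorted label order.
    external_results : DataFrame, optional
        A results table fitted by an external engine (must have log2fc,
        p_value columns indexed like ``table``); when given it is
        BH-adjusted and returned unchanged otherwise.

    Returns
    -------
    DataFrame
        base_mean, log2fc, p_value, p_adj, significant (p_adj < alpha).
    """
    if external_results is not None:
        out = external_results.copy()
        out["p_adj"] = multipletests(out["p_value"].fillna(1.0), method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
        return out
    groups = sorted(set(design.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    cols = {g: [s for s in table.columns if design.get(s) == g] for g in groups}
    for g, cs in cols.items():
        if len(cs) < 2:
            raise ValueError(f"group {g!r} has {len(cs)} replicates (need >= 2)")
    sf = size_factors(table)
    norm = table / sf
    g1, g2 = groups
    x1 = norm[cols[g1]].to_numpy(dtype=float)
    x2 = norm[cols[g2]].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    n1, n2 = x1.shape[1], x2.shape[1]
    # method-of-moments NB dispersion, pooled across both groups:
    # Var = mu + alpha * mu^2  =>  alpha = (Var - mu) / mu^2
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    mu = (m1 * n1 + m2 * n2) / (n1 + n2)
    pooled_var = (v1 * (n1 - 1) + v2 * (n2 - 1)) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.clip((pooled_var - mu) / np.where(mu > 0, mu**2, np.nan), 0, None)
    disp = np.nan_to_num(disp, nan=0.0)
    eps = 0.5  # pseudocount stabilizes empty groups
    log2fc = np.log2((m2 + eps) / (m1 + eps))
    # delta method on log means with NB variance
    var_log1 = (m1 + disp * m1**2) / np.maximum(n1 * (m1 + eps) ** 2, 1e-300)
    var_log2 = (m2 + disp * m2**2) / np.maximum(n2 * (m2 + eps) ** 2, 1e-300)
    se = np.sqrt(var_log1 + var_log2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log((m2 + eps) / (m1 + eps)) / se
    z = np.where(se == 0, 0.0, z)
    p = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "base_mean": mu,
            "log2fc": log2fc,
            "p_value": p,
        },
        index=table.index,
    )
    out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out
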