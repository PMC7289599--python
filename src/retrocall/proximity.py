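"""TSS-proximity enrichment of deregulated genes near TE families or peaks.

For a feature set (one TE family, or a ChIP peak set), a gene is *near*
when any feature edge lies within a window of its TSS (both flanks, strand
ignored, closed boundary: a feature exactly ``window`` bp away counts).
With ``p`` the fraction of all genes near the features, ``n`` the number
of genes of one status group (e.g. upregulated) and ``x`` how many of
those are near, a right-tailed binomial test gives
``P(X >= x), X ~ Binomial(n, p)``. Adjustment is Benjamini–Hochberg within
each repeat class (LTR and LINE separately).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "status"]
STATUSES = ("up", "down", "ns")


def _merge_union(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of possibly overlapping intervals, sorted."""
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    ms, me = [], []
    cur_s, cur_e = s[0], e[0]
    for i in range(1, len(s)):
        if s[i] <= cur_e:
            cur_e = max(cur_e, e[i])
        else:
            ms.append(cur_s)
            me.append(cur_e)
            cur_s, cur_e = s[i], e[i]
    ms.append(cur_s)
    me.append(cur_e)
    return np.asarray(ms), np.asarray(me)


def nearest_feature_distance(
    genes: pd.DataFrame, features: pd.DataFrame
) -> np.ndarray:
    """Per gene, distance (bp) from the TSS point to the nearest feature
    edge: 0 inside a feature, inf when the chromosome has no features.

    The nearest-edge distance to any feature equals the distance to the
    union of the features, so intervals are merged first and the lookup is
    a binary search.
    """
    if genes.empty:
        raise ValueError("no genes given")
    out = np.full(len(genes), np.inf)
    if features.empty:
        return out
    gchrom = genes["chrom"].to_numpy()
    tss = genes["tss"].to_numpy()
    for chrom, sub in features.groupby("chrom"):
        mask = gchrom == chrom
        if not mask.any():
            continue
        ms, me = _merge_union(sub["start"].to_numpy(), sub["end"].to_numpy())
        t = tss[mask]
        j = np.searchsorted(ms, t, side="right") - 1
        inside = (j >= 0) & (t < me[np.clip(j, 0, None)])
        # distance to previous interval's last base and next interval's first
        prev_end = np.where(j >= 0, me[np.clip(j, 0, None)] - 1, -np.inf)
        nxt = np.clip(j + 1, 0, len(ms) - 1)
        next_start = np.where(j + 1 < len(ms), ms[nxt], np.inf)
        dist = np.minimum(np.abs(t - prev_end), np.abs(next_start - t))
        out[mask] = np.where(inside, 0.0, dist)
    return out


def tss_near_features(
    genes: pd.DataFrame, features: pd.DataFrame, window: int = 100_000
) -> np.ndarray:
    """Boolean per gene: any feature within ``window`` bp of the TSS
    (closed boundary: a feature edge exactly ``window`` bp away counts).

    Distance is from the TSS point to the nearest feature edge; a TSS
    inside a feature has distance 0.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    return nearest_feature_distance(genes, features) <= window


@dataclass
class NearCounts:
    """Per-status counts of genes near a feature set."""

    x_by_status: dict
    n_by_status: dict
    p_global: float


def genes_near_features(
    genes: pd.DataFrame, features: pd.DataFrame, window: int = 100_000
) -> NearCounts:
    """Count genes near features, per deregulation status.

    Returns per-status near counts ``x``, group sizes ``n``, and the
    global fraction ``p = (#genes near) / (#genes)`` used as the binomial
    null probability.
    """
    near = tss_near_features(genes, features, window)
    x_by_status = {}
    n_by_status = {}
    for status, sub in genes.groupby("status"):
        mask = genes["status"].to_numpy() == status
        x_by_status[status] = int(near[mask].sum())
        n_by_status[status] = int(mask.sum())
    p_global = float(near.mean())
    return NearCounts(x_by_status=x_by_status, n_by_status=n_by_status, p_global=p_global)


def binomial_enrichment(x: int, n: int, p: float) -> float:
    """Right-tailed binomial p-value ``P(X >= x)`` for ``X ~ Bin(n, p)``."""
    if not (0 <= p <= 1):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if x == 0:
        return 1.0
    return float(stats.binomtest(x, n, p, alternative="greater").pvalue)


def adjust_by_class(
    results: pd.DataFrame, class_map: dict, alpha: float = 0.1
) -> pd.DataFrame:
    """BH adjustment within each repeat class (LTR / LINE) separately.

    ``results`` needs family and p_raw columns; ``class_map`` assigns every
    family to a class. Flags adjusted p < ``alpha``.
    """
    missing = [f for f in results["family"] if f not in class_map]
    if missing:
        raise ValueError(f"families without a class: {sorted(set(missing))}")
    out = results.copy()
    out["repeat_class"] = out["family"].map(class_map)
    out["p_adj"] = np.nan
    for _, idx in out.groupby("repeat_class").groups.items():
        out.loc[idx, "p_adj"] = multipletests(out.loc[idx, "p_raw"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out


def proximity_enrichment(
    genes: pd.DataFrame,
    features_by_family: dict,
    class_map: dict,
    window: int = 100_000,
    status: str = "up",
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Full per-family proximity screen for one status group.

    Returns a table: family, repeat_class, x, n, p_global, ratio
    (x / (n * p_global)), p_raw, p_adj, significant.
    """
    rows = []
    for family, features in features_by_family.items():
        counts = genes_near_features(genes, features, window)
        x = counts.x_by_status.get(status, 0)
        n = counts.n_by_status.get(status, 0)
        p = counts.p_global
        p_raw = binomial_enrichment(x, n, p) if n > 0 else 1.0
        ratio = (x / (n * p)) if n > 0 and p > 0 else np.nan
        rows.append(
            dict(family=family, x=x, n=n, p_global=p, ratio=ratio, p_raw=p_raw)
        )
    results = pd.DataFrame(rows)
    return adjust_by_class(results, class_map, alpha=alpha)


DEFAULT_BANDS = ((0, 20_000), (20_000, 50_000), (50_000, 100_000))


def distance_banded_fractions(
    genes: pd.DataFrame,
    features: pd.DataFrame,
    bands=DEFAULT_BANDS,
    status: str = "up",
) -> pd.DataFrame:
    """Fraction of genes with the given status among genes whose nearest
    feature falls in each distance band (half-open bands, closed at the
    upper edge of the last band)."""
    nearest = nearest_feature_distance(genes, features)
    is_status = genes["status"].to_numpy() == status
    rows = []
    for lo, hi in bands:
        in_band = (nearest >= lo) & (nearest < hi)
        n = int(in_band.sum())
        rows.append(
            dict(
                band=f"{lo}-{hi}",
                n_genes=n,
                fraction=float(is_status[in_band].mean()) if n else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["band", "n_genes", "fraction"])
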