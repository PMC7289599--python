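"""ChIP-seq peak <-> repeat-family enrichment.

Workflow: peaks are standardized to fixed-width windows around their
summits, peak sets called against two controls are intersected, a
stringency tier is chosen by peak count, and per repeat family a
right-tailed Fisher's exact test measures over-representation of peak
overlap, with Benjamini–Hochberg adjustment across all dataset x family
cells jointly.

The 2x2 table emulates an interval Fisher utility: with ``a`` peaks
overlapping the family (>= ``min_peak_overlap_fraction`` of the peak
inside family intervals), ``b`` peaks not overlapping, ``c`` family
intervals not overlapped by any peak, the remainder
``d = genome_size / (mean peak length + mean family interval length)
- a - b - c`` (floored at 0) approximates the number of genomic slots
carrying neither feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import RepeatAnnotation
from .intervals import IntervalIndex

TIER_ORDER = ("high", "medium", "low")


def standardize_peaks(
    peaks: pd.DataFrame, chrom_sizes: dict, width: int = 200
) -> pd.DataFrame:
    """Scale every peak to ``width`` bp centered on its summit.

    ``peaks`` needs chrom and summit (absolute bp) columns. Windows
    extending past chromosome bounds are clipped (and flagged), so output
    widths are <= ``width`` and == ``width`` when unclipped.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    half = width // 2
    out = peaks.copy()
    start = out["summit"].to_numpy() - half
    end = start + width
    lim = out["chrom"].map(chrom_sizes).to_numpy()
    if np.isnan(lim.astype(float)).any():
        missing = sorted(set(out["chrom"]) - set(chrom_sizes))
        raise ValueError(f"chromosomes without sizes: {missing}")
    clipped_start = np.maximum(start, 0)
    clipped_end = np.minimum(end, lim.astype(int))
    out["start"] = clipped_start
    out["end"] = clipped_end
    out["clipped"] = (clipped_start != start) | (clipped_end != end)
    return out


def select_stringency_tier(
    peaksets: dict, min_peaks: int = 50
) -> tuple[str, pd.DataFrame, bool]:
    """Most stringent tier with at least ``min_peaks`` peaks.

    ``peaksets`` maps tier name (``high``/``medium``/``low``) to a peak
    table. Returns (tier, peaks, warning) where ``warning`` is True when
    no tier reaches ``min_peaks`` and the lowest available tier is
    returned.
    """
    if not peaksets:
        raise ValueError("no peak sets given")
    available = [t for t in TIER_ORDER if t in peaksets]
    for tier in available:
        if len(peaksets[tier]) >= min_peaks:
            return tier, peaksets[tier], False
    tier = available[-1]
    return tier, peaksets[tier], True


def intersect_controls(
    peaks_vs_input: pd.DataFrame, peaks_vs_mock: pd.DataFrame
) -> pd.DataFrame:
    """Consensus peaks: keep input-control peaks that overlap (>= 1 bp) any
    mock-control peak."""
    if peaks_vs_input.empty or peaks_vs_mock.empty:
        return peaks_vs_input.iloc[0:0].copy()
    idx = IntervalIndex(peaks_vs_mock[["chrom", "start", "end"]].reset_index(drop=True))
    keep = [
        bool(idx.query(r.chrom, r.start, r.end))
        for r in peaks_vs_input.itertuples()
    ]
    return peaks_vs_input[np.asarray(keep)].reset_index(drop=True)


def fisher_table(
    peaks: pd.DataFrame,
    family_df: pd.DataFrame,
    genome_size: int,
    min_peak_overlap_fraction: float = 0.25,
) -> tuple[int, int, int, int]:
    """Build the 2x2 table for one peak set against one family's intervals."""
    idx = IntervalIndex(family_df.reset_index(drop=True))
    fam = family_df.reset_index(drop=True)
    n_overlap = 0
    overlapped_fam: set = set()
    for r in peaks.itertuples():
        plen = r.end - r.start
        best = 0
        for j in idx.query(r.chrom, r.start, r.end):
            row = fam.loc[j]
            ov = min(r.end, row["end"]) - max(r.start, row["start"])
            if ov > 0:
                best = max(best, ov)
                overlapped_fam.add(j)
        if plen > 0 and best >= min_peak_overlap_fraction * plen:
            n_overlap += 1
    a = n_overlap
    b = len(peaks) - a
    c = len(fam) - len(overlapped_fam)
    mean_peak = float(np.mean(peaks["end"] - peaks["start"])) if len(peaks) else 0.0
    mean_fam = float(np.mean(fam["end"] - fam["start"])) if len(fam) else 0.0
    denom = mean_peak + mean_fam
    if denom <= 0:
        d = 0
    else:
        d = max(0, int(genome_size / denom) - a - b - c)
    return a, b, c, d


def fisher_right_tail(a: int, b: int, c: int, d: int) -> float:
    """Right-tailed Fisher's exact p for a 2x2 table."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def fisher_enrichment(
    peaks_by_dataset: dict,
    annotation: RepeatAnnotation,
    genome_size: int,
    min_peak_overlap_fraction: float = 0.25,
    significance_alpha: float = 1e-5,
) -> pd.DataFrame:
    """Peak-overlap enrichment matrix across datasets and repeat families.

    Parameters
    ----------
    peaks_by_dataset : dict
        dataset name -> standardized peak table.
    annotation : RepeatAnnotation
        Families are taken from the ``family`` column.
    genome_size : int
        Effective genome size in bp.
    significance_alpha : float
        Adjusted-p cutoff for the ``significant`` flag.

    Returns
    -------
    DataFrame
        dataset, family, a/b/c/d, overlap (== a), p_raw, p_adj,
        significant. BH adjustment is joint across all cells.
    """
    total_span = int((annotation.df["end"] - annotation.df["start"]).sum())
    if genome_size < total_span:
        raise ValueError(
            f"genome_size {genome_size} smaller than total annotation span {total_span}"
        )
    rows = []
    for dataset, peaks in peaks_by_dataset.items():
        for family, fam_df in annotation.df.groupby("family", sort=True):
            a, b, c, d = fisher_table(
                peaks, fam_df, genome_size, min_peak_overlap_fraction
            )
            rows.append(
                dict(
                    dataset=dataset,
                    family=family,
                    a=a,
                    b=b,
                    c=c,
                    d=d,
                    overlap=a,
                    p_raw=fisher_right_tail(a, b, c, d),
                )
            )
    out = pd.DataFrame(rows)
    if out.empty:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < significance_alpha
    return out


def signal_at_peaks(
    coverage: dict,
    peaks: pd.DataFrame,
    family_of_peak: pd.Series,
) -> pd.DataFrame:
    """Mean per-base coverage over the peaks assigned to each family.

    ``coverage`` maps chromosome -> per-base numpy array. Families with no
    assigned peaks are absent from the output (missing, not zero).
    """
    rows = []
    peaks = peaks.assign(_family=family_of_peak.to_numpy())
    for family, sub in peaks.groupby("_family", sort=True):
        total = 0.0
        bases = 0
        for r in sub.itertuples():
            track = coverage.get(r.chrom)
            if track is None:
                raise KeyError(f"no coverage for chromosome {r.chrom!r}")
            total += float(np.sum(track[r.start : r.end]))
            bases += r.end - r.start
        rows.append(dict(family=family, mean_signal=total / bases if bases else np.nan,
                         n_peaks=len(sub)))
    return pd.DataFrame(rows, columns=["family", "mean_signal", "n_peaks"])
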