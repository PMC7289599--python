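"""Capture-seq insertion-site discovery.

The pipeline mirrors a targeted-capture screen for new retrotransposon
insertions: read pairs are classified into (unique anchor, repeat mate)
pairs, anchors are clustered into candidate loci, per-sample support is
normalized to reads per million unique repeat-paired reads, loci passing
the RPM threshold are called, and loci explained by annotated elements or
known polymorphic insertions are diverted to a separate stream.

Anchor classification rule: a mate is *repeat-classified* when it overlaps
a target-family repeat fragment by at least half the read length; a pair is
kept when exactly one mate is repeat-classified and the other mate maps
uniquely, is not a duplicate and is not itself repeat-classified. The
unique mate (the *anchor*) localizes the insertion junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import RepeatAnnotation
from .intervals import IntervalIndex, merge_sorted_intervals

logger = logging.getLogger(__name__)

#: repeat families captured by the two probe sets
ETN_FAMILIES = ("RLTRETN", "MMETn-int", "ETnERV-int", "ETnERV2-int", "ETnERV3-int")
MULV_FAMILIES = ("RLTR4", "RLTR4_MM-int", "MuLV-int")

ANCHOR_COLUMNS = ["sample_id", "chrom", "start", "end", "strand", "family_set", "mate_family"]


@dataclass
class CallerConfig:
    """Constants of the calling pipeline (all from the screen design)."""

    min_overlap_fraction: float = 0.5
    merge_distance: int = 1000
    rpm_threshold: float = 10.0
    exclusion_distance: int = 1000
    family_sets: dict = field(
        default_factory=lambda: {
            "ETn": list(ETN_FAMILIES),
            "MuLV": list(MULV_FAMILIES),
        }
    )
    blocklist: pd.DataFrame | None = None  # chrom/start/end of known polymorphic loci

    def __post_init__(self) -> None:
        if self.min_overlap_fraction <= 0 or self.merge_distance <= 0:
            raise ValueError("thresholds must be > 0")
        if self.rpm_threshold <= 0 or self.exclusion_distance <= 0:
            raise ValueError("thresholds must be > 0")
        if not self.family_sets or any(not v for v in self.family_sets.values()):
            raise ValueError("family sets must be non-empty")

    def family_to_set(self) -> dict:
        out = {}
        for set_name, fams in self.family_sets.items():
            for f in fams:
                out[f] = set_name
        return out

    def target_families(self) -> set:
        return set(self.family_to_set())


def deduplicate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR/optical duplicates: within a sample, pairs with
    identical (chrom, start, strand) of both mates keep one representative.
    Pairs flagged ``dup1``/``dup2`` are dropped as well."""
    keep = pairs.drop_duplicates(
        subset=["sample_id", "chrom1", "start1", "strand1", "chrom2", "start2", "strand2"]
    )
    if "dup1" in keep.columns:
        keep = keep[~(keep["dup1"].astype(bool) | keep["dup2"].astype(bool))]
    return keep.reset_index(drop=True)


def _repeat_overlap(
    pairs: pd.DataFrame, mate: int, index: IntervalIndex, ann: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair best overlap (bp) of mate ``mate`` with any target repeat
    fragment, and the family of the best fragment."""
    n = len(pairs)
    best = np.zeros(n, dtype=int)
    fam = np.array([""] * n, dtype=object)
    chroms = pairs[f"chrom{mate}"].to_numpy()
    starts = pairs[f"start{mate}"].to_numpy()
    ends = pairs[f"end{mate}"].to_numpy()
    for i in range(n):
        for ridx in index.query(chroms[i], starts[i], ends[i]):
            row = ann.loc[ridx]
            ov = min(ends[i], row["end"]) - max(starts[i], row["start"])
            if ov > best[i]:
                best[i] = ov
                fam[i] = row["family"]
    return best, fam


def classify_reads(
    pairs: pd.DataFrame, annotation: RepeatAnnotation, config: CallerConfig
) -> pd.DataFrame:
    """Classify read pairs into anchored pairs.

    Parameters
    ----------
    pairs : DataFrame
        Read-pair table (``sample_id``, and per-mate ``chrom/start/end/
        strand/unique/dup`` columns suffixed 1 and 2).
    annotation : RepeatAnnotation
        Repeat annotation; only fragments of the configured target families
        are considered for repeat classification.
    config : CallerConfig

    Returns
    -------
    DataFrame
        One row per anchored pair: sample_id, anchor coordinates, the
        family set (e.g. ``ETn``/``MuLV``) and repeat family of the mate.
    """
    pairs = deduplicate_pairs(pairs)
    target = annotation.subset_families(config.target_families())
    known_chroms = set(annotation.df["chrom"])
    bad = ~(pairs["chrom1"].isin(known_chroms) & pairs["chrom2"].isin(known_chroms))
    if bad.any():
        logger.warning("skipping %d pairs on unannotated chromosomes", int(bad.sum()))
        pairs = pairs[~bad].reset_index(drop=True)
    if pairs.empty:
        return pd.DataFrame(columns=ANCHOR_COLUMNS)

    index = target.index()
    fam_to_set = config.family_to_set()
    out_rows = []
    ov1, fam1 = _repeat_overlap(pairs, 1, index, target.df)
    ov2, fam2 = _repeat_overlap(pairs, 2, index, target.df)
    len1 = (pairs["end1"] - pairs["start1"]).to_numpy()
    len2 = (pairs["end2"] - pairs["start2"]).to_numpy()
    rep1 = ov1 >= config.min_overlap_fraction * len1
    rep2 = ov2 >= config.min_overlap_fraction * len2
    uniq1 = pairs["unique1"].to_numpy(dtype=bool)
    uniq2 = pairs["unique2"].to_numpy(dtype=bool)

    # anchor eligibility: unique, non-duplicate (dedup done above), not
    # itself repeat-classified
    anchor1 = uniq1 & ~rep1 & rep2
    anchor2 = uniq2 & ~rep2 & rep1
    for mate, mask, fam in ((1, anchor1, fam2), (2, anchor2, fam1)):
        sub = pairs.loc[mask]
        if sub.empty:
            continue
        out_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sub["sample_id"].to_numpy(),
                    "chrom": sub[f"chrom{mate}"].to_numpy(),
                    "start": sub[f"start{mate}"].to_numpy(),
                    "end": sub[f"end{mate}"].to_numpy(),
                    "strand": sub[f"strand{mate}"].to_numpy(),
                    "mate_family": fam[mask],
                }
            )
        )
    if not out_rows:
        return pd.DataFrame(columns=ANCHOR_COLUMNS)
    anchors = pd.concat(out_rows, ignore_index=True)
    anchors["family_set"] = anchors["mate_family"].map(fam_to_set)
    anchors = anchors.sort_values(["family_set", "chrom", "start", "end", "sample_id"])
    return anchors[ANCHOR_COLUMNS].reset_index(drop=True)


def anchor_totals(anchors: pd.DataFrame) -> pd.Series:
    """Per-(sample, family set) totals of unique repeat-paired reads — the
    RPM denominators."""
    return anchors.groupby(["sample_id", "family_set"]).size()


def cluster_anchors(
    anchors: pd.DataFrame, config: CallerConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster anchors into candidate loci (``bedtools merge -d`` style).

    Anchors of one family set, on one chromosome, whose intervals are
    separated by at most ``merge_distance`` bp merge into one locus across
    all samples jointly.

    Returns
    -------
    (loci, support)
        ``loci``: locus_id, chrom, start, end, family_set.
        ``support``: locus_id, sample_id, support (anchor count).
    """
    loci_rows = []
    support_rows = []
    if not anchors.empty:
        for (fset, chrom), sub in anchors.groupby(["family_set", "chrom"], sort=True):
            sub = sub.sort_values(["start", "end"])
            labels = merge_sorted_intervals(
                sub["start"].to_numpy(), sub["end"].to_numpy(), config.merge_distance
            )
            sub = sub.assign(_label=labels)
            for label, grp in sub.groupby("_label", sort=True):
                locus_id = f"{fset}:{chrom}:{int(grp['start'].min())}-{int(grp['end'].max())}"
                loci_rows.append(
                    dict(
                        locus_id=locus_id,
                        chrom=chrom,
                        start=int(grp["start"].min()),
                        end=int(grp["end"].max()),
                        family_set=fset,
                    )
                )
                counts = grp.groupby("sample_id").size()
                for sample_id, n in counts.items():
                    support_rows.append(
                        dict(locus_id=locus_id, sample_id=sample_id, support=int(n))
                    )
    loci = pd.DataFrame(loci_rows, columns=["locus_id", "chrom", "start", "end", "family_set"])
    support = pd.DataFrame(support_rows, columns=["locus_id", "sample_id", "support"])
    return loci, support


def normalize_support(
    support: pd.DataFrame, loci: pd.DataFrame, totals: pd.Series
) -> pd.DataFrame:
    """Fill reads-per-million: ``rpm = 1e6 * support / total`` where the
    total is the sample's count of unique repeat-paired reads for the
    locus's family set.

    Raises
    ------
    ValueError
        If a represented (sample, family set) has no or zero total.
    """
    if support.empty:
        out = support.copy()
        out["rpm"] = pd.Series(dtype=float)
        return out
    fset_of = dict(zip(loci["locus_id"], loci["family_set"]))
    out = support.copy()
    out["family_set"] = out["locus_id"].map(fset_of)
    rpm = np.empty(len(out))
    for i, row in enumerate(out.itertuples()):
        key = (row.sample_id, row.family_set)
        total = totals.get(key, 0)
        if total is None or total <= 0:
            raise ValueError(
                f"no unique repeat-paired read total for sample {row.sample_id!r} "
                f"(family set {row.family_set!r})"
            )
        rpm[i] = 1e6 * row.support / total
    out["rpm"] = rpm
    return out.drop(columns=["family_set"])


def partition_loci(
    loci: pd.DataFrame, annotation: RepeatAnnotation, config: CallerConfig
) -> pd.Series:
    """Assign each locus to a stream: ``annotated_proximal`` if it lies
    within ``exclusion_distance`` of a target-family repeat of the same
    family set or intersects the blocklist, else ``novel``."""
    streams = []
    block_index = (
        IntervalIndex(config.blocklist)
        if config.blocklist is not None and len(config.blocklist)
        else None
    )
    set_indexes = {
        fset: annotation.subset_families(fams).index()
        for fset, fams in config.family_sets.items()
    }
    for row in loci.itertuples():
        idx = set_indexes.get(row.family_set)
        proximal = idx is not None and idx.any_within(
            row.chrom, row.start, row.end, config.exclusion_distance
        )
        blocked = block_index is not None and bool(
            block_index.query(row.chrom, row.start, row.end)
        )
        streams.append("annotated_proximal" if (proximal or blocked) else "novel")
    return pd.Series(streams, index=loci.index, name="stream")


def call_insertions(
    loci: pd.DataFrame,
    support: pd.DataFrame,
    annotation: RepeatAnnotation,
    config: CallerConfig,
    pedigree=None,
) -> pd.DataFrame:
    """Apply the RPM threshold and the annotation/blocklist partition.

    A locus is called in a sample when its RPM is at least
    ``rpm_threshold`` ("at least": a tie at the threshold is a call). Calls
    at loci explained by annotated repeats or the blocklist are retained in
    the ``annotated_proximal`` stream (needed for recall and for the
    germline support comparison); the rest form the ``novel`` stream.

    Returns a call table: locus_id, chrom, start, end, family_set,
    sample_id, animal_id (when a pedigree is given), support, rpm, stream.
    """
    if "rpm" not in support.columns:
        raise ValueError("support table lacks rpm; run normalize_support first")
    streams = partition_loci(loci, annotation, config)
    loci = loci.assign(stream=streams)
    calls = support[support["rpm"] >= config.rpm_threshold].merge(loci, on="locus_id")
    if pedigree is not None:
        calls["animal_id"] = [pedigree.animal_of(s) for s in calls["sample_id"]]
    else:
        calls["animal_id"] = calls["sample_id"]
    cols = [
        "locus_id",
        "chrom",
        "start",
        "end",
        "family_set",
        "sample_id",
        "animal_id",
        "support",
        "rpm",
        "stream",
    ]
    return calls[cols].sort_values(["locus_id", "sample_id"]).reset_index(drop=True)


@dataclass
class RecallReport:
    """Per-sample recovery of intact reference elements."""

    per_sample: dict
    median: float
    n_elements: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample_id": list(self.per_sample), "recall": list(self.per_sample.values())}
        )
        return df


def compute_recall(
    loci: pd.DataFrame,
    support: pd.DataFrame,
    truth_elements,
    config: CallerConfig,
    window: int = 1000,
) -> RecallReport:
    """Fraction of intact truth elements recovered per sample.

    An element counts as recovered in a sample when a supported locus
    (RPM >= threshold, *before* the annotation-exclusion step — the
    exclusion would otherwise remove every reference element) lies within
    ``window`` bp of either probed LTR terminus (the 5' end of the 5' LTR
    or the 3' end of the 3' LTR).
    """
    truth = [t for t in truth_elements if t.intact]
    if not truth:
        raise ValueError("empty truth set")
    merged = support[support["rpm"] >= config.rpm_threshold].merge(
        loci, on="locus_id"
    )
    samples = sorted(support["sample_id"].unique())
    per_sample = {}
    for sample in samples:
        sub = merged[merged["sample_id"] == sample]
        idx = IntervalIndex(sub[["chrom", "start", "end"]].reset_index(drop=True))
        hit = 0
        for t in truth:
            for pos in (t.ltr5.start, t.ltr3.end):
                if idx.any_within(t.span.chrom, pos, pos + 1, window):
                    hit += 1
                    break
        per_sample[sample] = hit / len(truth)
    median = float(np.median(list(per_sample.values()))) if per_sample else 0.0
    return RecallReport(per_sample=per_sample, median=median, n_elements=len(truth))


def raw_counts_at_loci(anchors: pd.DataFrame, loci: pd.DataFrame) -> pd.DataFrame:
    """Anchored-read counts per (locus, sample) with no threshold — the
    "not a single read" evidence used by the de novo ancestor rule.
    Missing (locus, sample) combinations mean zero reads."""
    rows = []
    if not anchors.empty and not loci.empty:
        by_set = {
            fset: sub.sort_values(["chrom", "start"])
            for fset, sub in anchors.groupby("family_set")
        }
        for row in loci.itertuples():
            sub = by_set.get(row.family_set)
            if sub is None:
                continue
            m = sub[
                (sub["chrom"] == row.chrom)
                & (sub["end"] > row.start)
                & (sub["start"] < row.end)
            ]
            for sample_id, n in m.groupby("sample_id").size().items():
                rows.append(
                    dict(locus_id=row.locus_id, sample_id=sample_id, count=int(n))
                )
    return pd.DataFrame(rows, columns=["locus_id", "sample_id", "count"])


def run_caller(
    pairs: pd.DataFrame,
    annotation: RepeatAnnotation,
    config: CallerConfig | None = None,
    pedigree=None,
):
    """Convenience wrapper running the full calling pipeline.

    Returns a dict with anchors, loci, support (with RPM), calls and raw
    per-locus read counts.
    """
    config = config or CallerConfig()
    anchors = classify_reads(pairs, annotation, config)
    loci, support = cluster_anchors(anchors, config)
    if not support.empty:
        support = normalize_support(support, loci, anchor_totals(anchors))
    else:
        support["rpm"] = pd.Series(dtype=float)
    calls = call_insertions(loci, support, annotation, config, pedigree=pedigree)
    raw = raw_counts_at_loci(anchors, loci)
    return dict(anchors=anchors, loci=loci, support=support, calls=calls, raw_counts=raw)
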