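"""Readers and writers for the pipeline's file formats.

Read pairs travel as a BED-pair TSV (one row per pair, both mates) or as
SAM; peaks as narrowPeak; coverage as bedGraph; calls as BED9+ TSV. All
in-memory coordinates are 0-based half-open; SAM conversion handles the
1-based shift.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

try:
    import pysam
except ImportError:  # pragma: no cover - optional at runtime
    pysam = None


def write_pairs_tsv(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    for col in ("unique1", "dup1", "unique2", "dup2"):
        df[col] = df[col].astype(bool)
    return df


def write_pairs_sam(pairs: pd.DataFrame, path, chrom_sizes: dict) -> None:
    """Write pairs as a (text) SAM file; the unique flag is encoded as
    MAPQ 60 vs 0, the duplicate flag as the usual FLAG bit."""
    if pysam is None:
        raise RuntimeError("pysam is required for SAM output")
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in sorted(chrom_sizes.items())],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        refs = {c: i for i, c in enumerate(sorted(chrom_sizes))}
        for i, row in enumerate(pairs.itertuples()):
            for mate in (1, 2):
                a = pysam.AlignedSegment()
                a.query_name = f"{row.sample_id}:pair{i}"
                a.reference_id = refs[getattr(row, f"chrom{mate}")]
                a.reference_start = int(getattr(row, f"start{mate}"))
                length = int(getattr(row, f"end{mate}") - getattr(row, f"start{mate}"))
                a.cigarstring = f"{length}M"
                a.query_sequence = "N" * length
                flag = 0x1 | (0x40 if mate == 1 else 0x80)
                if getattr(row, f"strand{mate}") == "-":
                    flag |= 0x10
                if getattr(row, f"dup{mate}"):
                    flag |= 0x400
                a.flag = flag
                a.mapping_quality = 60 if getattr(row, f"unique{mate}") else 0
                a.set_tag("RG", str(row.sample_id))
                out.write(a)


def read_pairs_sam(path) -> pd.DataFrame:
    """Read a SAM produced by :func:`write_pairs_sam` (or equivalent:
    paired, RG tag per sample, MAPQ >= 30 meaning unique)."""
    if pysam is None:
        raise RuntimeError("pysam is required for SAM input")
    mates: dict = {}
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            key = a.query_name
            rec = dict(
                chrom=a.reference_name,
                start=a.reference_start,
                end=a.reference_end,
                strand="-" if a.is_reverse else "+",
                unique=a.mapping_quality >= 30,
                dup=a.is_duplicate,
                sample=a.get_tag("RG") if a.has_tag("RG") else "sample",
            )
            mates.setdefault(key, {})[1 if a.is_read1 else 2] = rec
    rows = []
    for key, m in mates.items():
        if 1 not in m or 2 not in m:
            continue
        row = {"sample_id": m[1]["sample"]}
        for mate in (1, 2):
            for field in ("chrom", "start", "end", "strand", "unique", "dup"):
                row[f"{field}{mate}"] = m[mate][field]
        rows.append(row)
    return pd.DataFrame(rows)


def read_bed3(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def read_narrowpeak(path) -> pd.DataFrame:
    """narrowPeak: summit column (10th) is the offset from start."""
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "signal", "pvalue", "qvalue", "summit_offset",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    df["summit"] = df["start"] + df["summit_offset"]
    return df


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"],
            "end": peaks["end"],
            "name": peaks.get("name", pd.Series(["peak"] * len(peaks))),
            "score": peaks.get("score", 0),
            "strand": ".",
            "signal": peaks.get("signal", 0.0),
            "pvalue": peaks.get("pvalue", -1.0),
            "qvalue": -1.0,
            "summit_offset": peaks["summit"] - peaks["start"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, chrom_sizes: dict) -> dict:
    """bedGraph -> per-chromosome per-base float arrays."""
    cov = {c: np.zeros(int(l)) for c, l in chrom_sizes.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    for r in df.itertuples():
        if r.chrom in cov:
            cov[r.chrom][r.start : r.end] = r.value
    return cov


def write_calls_bed(calls: pd.DataFrame, path) -> None:
    """Calls as BED9+ TSV: locus interval, family set, sample, support,
    rpm, stream."""
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["start"],
            "end": calls["end"],
            "name": calls["locus_id"],
            "score": calls["support"],
            "strand": ".",
            "family_set": calls["family_set"],
            "sample_id": calls["sample_id"],
            "animal_id": calls["animal_id"],
            "rpm": calls["rpm"].round(4),
            "stream": calls["stream"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_truth_json(truth, path) -> None:
    events = [
        dict(
            event_id=e.event_id,
            chrom=e.locus.chrom,
            pos=e.locus.start,
            family=e.family,
            origin=e.origin,
            carriers=sorted(e.carrier_animals),
            fraction_by_sample=e.fraction_by_sample,
        )
        for e in truth.events
    ]
    with open(path, "w") as fh:
        json.dump({"events": events}, fh, indent=1)
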