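"""Repeat annotation container and I/O.

A repeat annotation is a table of repeat fragments; fragments belonging to
one element (e.g. the two LTRs and the internal region of an intact ERV)
share an ``insertion_id``, mirroring how RepeatMasker repeat IDs group
fragments of a single insertion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .intervals import IntervalIndex

COLUMNS = ["chrom", "start", "end", "strand", "family", "rep_class", "insertion_id"]

#: valid values for the ``rep_class`` column
REP_CLASSES = ("LTR", "internal", "other")


@dataclass
class RepeatAnnotation:
    """Repeat fragments with family, class and shared insertion ID."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        bad = set(self.df["rep_class"]) - set(REP_CLASSES)
        if bad:
            raise ValueError(f"unknown rep_class values: {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset_families(self, families) -> "RepeatAnnotation":
        fams = set(families)
        return RepeatAnnotation(self.df[self.df["family"].isin(fams)].copy())

    def index(self) -> IntervalIndex:
        return IntervalIndex(self.df)

    def element_spans(self) -> pd.DataFrame:
        """One row per insertion_id covering all its fragments."""
        g = self.df.groupby("insertion_id", sort=False)
        out = g.agg(
            chrom=("chrom", "first"),
            start=("start", "min"),
            end=("end", "max"),
            family=("family", "first"),
        ).reset_index()
        return out

    # ------------------------------------------------------------------ I/O
    def to_bed(self, path) -> None:
        """Write BED6+3: name column holds the family, the three extra
        columns hold family, class and insertion ID."""
        out = self.df.copy()
        bed = pd.DataFrame(
            {
                "chrom": out["chrom"],
                "start": out["start"],
                "end": out["end"],
                "name": out["family"],
                "score": 0,
                "strand": out["strand"].replace({".": "."}),
                "family": out["family"],
                "rep_class": out["rep_class"],
                "insertion_id": out["insertion_id"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "RepeatAnnotation":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=[
                "chrom",
                "start",
                "end",
                "name",
                "score",
                "strand",
                "family",
                "rep_class",
                "insertion_id",
            ],
            dtype={"chrom": str},
        )
        return cls(df[COLUMNS].copy())

    def to_repeatmasker_out(self, path) -> None:
        """Write a minimal RepeatMasker-style .out (1-based inclusive
        coordinates, repeat ID in the last column)."""
        with open(path, "w") as fh:
            fh.write(
                "   SW  perc perc perc  query      position in query"
                "              matching       repeat              position in  repeat\n"
                "score  div. del. ins.  sequence    begin     end    (left)"
                "    repeat         class/family         begin  end (left)   ID\n\n"
            )
            for i, row in self.df.iterrows():
                cls_fam = f"LTR/{row['family']}" if row["rep_class"] != "other" else row["family"]
                strand = "C" if row["strand"] == "-" else "+"
                fh.write(
                    f"  239  10.0  0.0  0.0  {row['chrom']} {row['start'] + 1} "
                    f"{row['end']} (0) {strand} {row['family']} {cls_fam} "
                    f"1 {row['end'] - row['start']} (0) {row['insertion_id']}\n"
                )

    @classmethod
    def from_repeatmasker_out(cls, path) -> "RepeatAnnotation":
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) < 15 or not parts[0][0].isdigit():
                    continue
                chrom, begin, end = parts[4], int(parts[5]), int(parts[6])
                strand = "-" if parts[8] == "C" else "+"
                family = parts[9]
                cls_fam = parts[10]
                rep_id = parts[14]
                if family.endswith("-int") or "int" in cls_fam.lower().split("/")[-1]:
                    rep_class = "internal"
                elif cls_fam.startswith("LTR"):
                    rep_class = "LTR"
                else:
                    rep_class = "other"
                rows.append(
                    dict(
                        chrom=chrom,
                        start=begin - 1,
                        end=end,
                        strand=strand,
                        family=family,
                        rep_class=rep_class,
                        insertion_id=str(rep_id),
                    )
                )
        return cls(pd.DataFrame(rows, columns=COLUMNS))
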