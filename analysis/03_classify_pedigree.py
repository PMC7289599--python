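"""Classify the called insertions against the pedigree.

Applies the germline rule (>= 2 full siblings, parents clean, no carrier
outside the siblings' descendants) before the single-animal de novo rule
(zero reads in all sampled ancestors), writes the per-locus classes and
the per-animal novel-insertion counts, and contrasts read support of
de novo (mosaic) vs germline loci with a one-sided rank-sum test.
"""

from pathlib import Path

import pandas as pd

from retrocall.classify import (
    classify_insertions,
    compare_support,
    per_animal_novel_counts,
)
from retrocall.pedigree import Pedigree

BASE = Path(__file__).resolve().parents[1]
SCREEN = BASE / "scratch" / "screen"
RESULTS = BASE / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    calls = pd.read_csv(SCREEN / "calls.tsv", sep="\t").rename(
        columns={"name": "locus_id", "score": "support"}
    )
    raw = pd.read_csv(SCREEN / "raw_counts.tsv", sep="\t")
    pedigree = Pedigree.from_tsv(SCREEN / "animals.tsv", SCREEN / "samples.tsv")

    classified = classify_insertions(calls, raw, pedigree)
    classified.assign(carriers=classified["carriers"].map(",".join)).to_csv(
        RESULTS / "classified.tsv", sep="\t", index=False
    )
    counts = per_animal_novel_counts(classified, pedigree)
    counts.to_csv(RESULTS / "per_animal_counts.tsv", sep="\t", index=False)

    annotated = calls[calls["stream"] == "annotated_proximal"]
    flank_support = annotated.groupby("locus_id")["support"].max().to_numpy()
    stats = compare_support(classified, calls, annotated_flank_support=flank_support)
    stats.tests.to_csv(RESULTS / "support_tests.tsv", sep="\t", index=False)

    truth = pd.read_csv(SCREEN / "truth.tsv", sep="\t")
    print("planted origins:", truth["origin"].value_counts().to_dict())
    print("classified:", classified["cls"].value_counts().to_dict())
    print("per-class median support:", stats.medians)
    for row in stats.tests.itertuples():
        print(f"{row.comparison}: rank-sum p = {row.p_value:.2e}")


if __name__ == "__main__":
    main()
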