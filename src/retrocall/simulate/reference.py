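"""Synthetic reference genomes carrying ERV-like elements.

The generator plants *intact* elements — two LTR fragments flanking an
internal fragment, all sharing one insertion ID — and solitary LTRs of
named families on one or more chromosomes, at least 2 kb apart, and
returns the annotation together with a per-element truth record.
Nucleotide sequence is optional and not generated by default (the pipeline
consumes aligned records, not bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..annotation import COLUMNS, RepeatAnnotation
from ..intervals import GenomicInterval

#: geometry of the simulated families; LTR/internal names follow the
#: RepeatMasker families the capture screen targets
FAMILY_MODELS = {
    "ETn": dict(ltr_family="RLTRETN", internal_family="MMETn-int", ltr_len=320, internal_len=4800),
    "MuLV": dict(ltr_family="RLTR4", internal_family="MuLV-int", ltr_len=520, internal_len=7200),
}

MIN_ELEMENT_GAP = 2000
EDGE_MARGIN = 5000
MAX_PLACEMENT_TRIES = 200


@dataclass(frozen=True)
class FamilyModel:
    """Sizes and fragment names of one simulated ERV family."""

    name: str
    ltr_family: str
    internal_family: str
    ltr_len: int
    internal_len: int

    @property
    def element_len(self) -> int:
        return 2 * self.ltr_len + self.internal_len

    @classmethod
    def get(cls, name: str) -> "FamilyModel":
        if isinstance(name, FamilyModel):
            return name
        try:
            return cls(name=name, **FAMILY_MODELS[name])
        except KeyError:
            raise ValueError(
                f"unknown family {name!r}; known: {sorted(FAMILY_MODELS)}"
            ) from None


@dataclass(frozen=True)
class ElementTruth:
    """Ground-truth record of one annotated element."""

    insertion_id: str
    family: str  # family-set name, e.g. "ETn"
    span: GenomicInterval
    ltr5: GenomicInterval
    ltr3: GenomicInterval
    intact: bool

    def __post_init__(self) -> None:
        if self.intact:
            if self.ltr5.end > self.ltr3.start:
                raise ValueError("5' LTR must precede 3' LTR")
            if not (self.span.start <= self.ltr5.start and self.ltr3.end <= self.span.end):
                raise ValueError("span must cover both LTRs")


@dataclass
class ReferenceBundle:
    """A synthetic genome: chromosome sizes, repeat annotation, element
    truth, and (optionally) sequence."""

    chrom_sizes: dict
    annotation: RepeatAnnotation
    intact_elements: list
    sequence: dict | None = None

    def validate(self) -> None:
        for row in self.annotation.df.itertuples():
            size = self.chrom_sizes.get(row.chrom)
            if size is None or row.start < 0 or row.end > size:
                raise ValueError(f"fragment outside chromosome bounds: {row}")


def _place_elements(
    rng: np.random.Generator,
    chrom_names: list,
    chrom_len: int,
    lengths: list,
    occupied: dict,
) -> list:
    """Place elements of given lengths >= MIN_ELEMENT_GAP apart; returns
    (chrom, start) per element or raises after bounded retries."""
    out = []
    for length in lengths:
        placed = False
        for _ in range(MAX_PLACEMENT_TRIES):
            chrom = chrom_names[rng.integers(len(chrom_names))]
            start = int(rng.integers(EDGE_MARGIN, chrom_len - EDGE_MARGIN - length))
            ok = all(
                start - (s + l) >= MIN_ELEMENT_GAP or s - (start + length) >= MIN_ELEMENT_GAP
                for s, l in occupied.get(chrom, [])
            )
            if ok:
                occupied.setdefault(chrom, []).append((start, length))
                out.append((chrom, start))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place element after bounded retries: genome too small"
            )
    return out


def make_reference(
    n_chroms: int = 1,
    chrom_len: int = 10_000_000,
    n_intact: int = 50,
    n_solo_ltr: int = 100,
    families=("ETn",),
    seed: int = 0,
) -> ReferenceBundle:
    """Generate a reference with intact elements and solitary LTRs.

    ``n_intact`` and ``n_solo_ltr`` apply per requested family. Elements
    are kept >= 2 kb apart; a genome too small to host them raises.
    Deterministic for a fixed seed.
    """
    models = [FamilyModel.get(f) for f in families]
    if n_intact < 0 or n_solo_ltr < 0 or n_chroms < 1:
        raise ValueError("counts must be >= 0 and n_chroms >= 1")
    max_elem = max((m.element_len for m in models), default=0)
    if models and chrom_len <= 10 * max_elem:
        raise ValueError(
            f"chrom_len {chrom_len} too small (need > 10 x element length {max_elem})"
        )
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_sizes = {c: chrom_len for c in chrom_names}
    occupied: dict = {}
    rows = []
    truths = []
    for model in models:
        intact_pos = _place_elements(
            rng, chrom_names, chrom_len, [model.element_len] * n_intact, occupied
        )
        for k, (chrom, start) in enumerate(intact_pos):
            iid = f"{model.name}_intact_{k:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            ltr5 = GenomicInterval(chrom, start, start + model.ltr_len, strand)
            internal = GenomicInterval(
                chrom, ltr5.end, ltr5.end + model.internal_len, strand
            )
            ltr3 = GenomicInterval(
                chrom, internal.end, internal.end + model.ltr_len, strand
            )
            for iv, fam, cls in (
                (ltr5, model.ltr_family, "LTR"),
                (internal, model.internal_family, "internal"),
                (ltr3, model.ltr_family, "LTR"),
            ):
                rows.append(
                    dict(
                        chrom=iv.chrom,
                        start=iv.start,
                        end=iv.end,
                        strand=strand,
                        family=fam,
                        rep_class=cls,
                        insertion_id=iid,
                    )
                )
            truths.append(
                ElementTruth(
                    insertion_id=iid,
                    family=model.name,
                    span=GenomicInterval(chrom, start, ltr3.end, strand),
                    ltr5=ltr5,
                    ltr3=ltr3,
                    intact=True,
                )
            )
        solo_pos = _place_elements(
            rng, chrom_names, chrom_len, [model.ltr_len] * n_solo_ltr, occupied
        )
        for k, (chrom, start) in enumerate(solo_pos):
            iid = f"{model.name}_solo_{k:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                dict(
                    chrom=chrom,
                    start=start,
                    end=start + model.ltr_len,
                    strand=strand,
                    family=model.ltr_family,
                    rep_class="LTR",
                    insertion_id=iid,
                )
            )
    df = pd.DataFrame(rows, columns=COLUMNS)
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    bundle = ReferenceBundle(
        chrom_sizes=chrom_sizes,
        annotation=RepeatAnnotation(df),
        intact_elements=truths,
    )
    bundle.validate()
    return bundle
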