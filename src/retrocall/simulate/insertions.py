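"""Planting ground-truth insertions on a pedigree.

Three origins are simulated:

* ``founder_polymorphic`` — a segregating insertion carried by a founder
  and transmitted to descendants by seeded Mendelian coin flips
  (heterozygous, one-half per offspring of a carrier).
* ``parental_germline`` — an insertion arising in the germ line of one
  mating's parent: carried by a subset (>= 2) of that litter, absent from
  the parents' somatic samples; carriers transmit onward at one half.
* ``embryonic_mosaic`` — an insertion in the developing embryo of exactly
  one animal, present in a fraction of cells (support is binomially
  thinned at read simulation; tissues of one animal overlap only
  partially when the fraction is < 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..intervals import GenomicInterval, IntervalIndex
from ..pedigree import Pedigree
from .reference import ReferenceBundle

ORIGINS = ("founder_polymorphic", "parental_germline", "embryonic_mosaic")

#: clearance between planted loci and annotated repeats / each other, in bp
PLANT_CLEARANCE = 6000
MAX_PLACEMENT_TRIES = 200


@dataclass(frozen=True)
class InsertionEvent:
    """One planted insertion with its carriers and per-sample cell
    fraction (1.0 = clonal)."""

    event_id: str
    locus: GenomicInterval
    family: str
    origin: str
    carrier_animals: frozenset
    fraction_by_sample: dict

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        for f in self.fraction_by_sample.values():
            if not (0 < f <= 1):
                raise ValueError("cell fraction must be in (0, 1]")


@dataclass
class InsertionTruthSet:
    events: list

    def by_origin(self) -> dict:
        out: dict[str, list] = {o: [] for o in ORIGINS}
        for e in self.events:
            out[e.origin].append(e)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                event_id=e.event_id,
                chrom=e.locus.chrom,
                pos=e.locus.start,
                family=e.family,
                origin=e.origin,
                carriers=",".join(sorted(e.carrier_animals)),
            )
            for e in self.events
        ]
        return pd.DataFrame(
            rows, columns=["event_id", "chrom", "pos", "family", "origin", "carriers"]
        )


def _transmit(pedigree: Pedigree, seeds: set, rng: np.random.Generator) -> set:
    """Mendelian transmission: starting carriers plus descendants, each
    offspring of a carrier parent inheriting with probability 1/2.
    Animals are visited in pedigree order (parents precede offspring in
    the generated tables)."""
    carriers = set(seeds)
    for a in pedigree.animal_ids():
        if a in carriers:
            continue
        sire, dam = pedigree.parents(a)
        if (sire in carriers) or (dam in carriers):
            if rng.random() < 0.5:
                carriers.add(a)
    return carriers


def _place_loci(
    reference: ReferenceBundle, n: int, rng: np.random.Generator
) -> list:
    ann_index = reference.annotation.index()
    chroms = sorted(reference.chrom_sizes)
    placed: list[GenomicInterval] = []
    for _ in range(n):
        ok = False
        for _try in range(MAX_PLACEMENT_TRIES):
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(
                rng.integers(PLANT_CLEARANCE, reference.chrom_sizes[chrom] - PLANT_CLEARANCE)
            )
            if ann_index.any_within(chrom, pos, pos + 1, PLANT_CLEARANCE):
                continue
            if any(
                p.chrom == chrom and abs(p.start - pos) < PLANT_CLEARANCE for p in placed
            ):
                continue
            placed.append(GenomicInterval(chrom, pos, pos + 1))
            ok = True
            break
        if not ok:
            raise RuntimeError("could not place insertion locus: genome too crowded")
    return placed


def plant_insertions(
    pedigree: Pedigree,
    reference: ReferenceBundle,
    rates: dict,
    seed: int = 0,
    family: str = "ETn",
    mosaic_cell_fraction=(0.1, 0.3),
    germline_mating: tuple | None = None,
    min_germline_carriers: int = 2,
) -> InsertionTruthSet:
    """Plant insertions of the requested origins on the pedigree.

    Parameters
    ----------
    rates : dict
        Event counts per origin, e.g. ``{"parental_germline": 3}``;
        missing origins default to 0. Counts are exact (conservation).
    mosaic_cell_fraction : float or (lo, hi)
        Fixed cell fraction, or a uniform range to draw from per event.
    germline_mating : (sire, dam), optional
        Mating whose litter receives germline events; defaults to the
        largest litter. Requesting germline events for a pair without
        offspring raises.
    """
    if not len(pedigree.animals):
        raise ValueError("empty pedigree")
    bad = set(rates) - set(ORIGINS)
    if bad:
        raise ValueError(f"unknown origins: {sorted(bad)}")
    counts = {o: int(rates.get(o, 0)) for o in ORIGINS}
    if any(v < 0 for v in counts.values()):
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    loci = _place_loci(reference, sum(counts.values()), rng)
    loci_iter = iter(loci)
    events = []

    def clonal_fractions(carriers: set) -> dict:
        return {
            s: 1.0 for a in sorted(carriers) for s in pedigree.samples_of(a)
        }

    # founder polymorphic
    founders = [
        a for a in pedigree.animal_ids() if pedigree.parents(a) == (None, None)
    ]
    founders_with_kids = [f for f in founders if pedigree.descendants(f)]
    for k in range(counts["founder_polymorphic"]):
        if not founders_with_kids:
            raise ValueError("no founder with offspring for a polymorphic event")
        founder = founders_with_kids[int(rng.integers(len(founders_with_kids)))]
        carriers = _transmit(pedigree, {founder}, rng)
        events.append(
            InsertionEvent(
                event_id=f"founder_{k:03d}",
                locus=next(loci_iter),
                family=family,
                origin="founder_polymorphic",
                carrier_animals=frozenset(carriers),
                fraction_by_sample=clonal_fractions(carriers),
            )
        )

    # parental germline
    if counts["parental_germline"]:
        matings = pedigree.matings()
        if germline_mating is not None:
            offspring = matings.get(tuple(germline_mating))
            if not offspring:
                raise ValueError(
                    f"mating {germline_mating} has no offspring in the pedigree"
                )
        else:
            if not matings:
                raise ValueError("pedigree has no matings for germline events")
            key = max(sorted(matings), key=lambda k: len(matings[k]))
            offspring = matings[key]
        if len(offspring) < min_germline_carriers:
            raise ValueError(
                f"litter of size {len(offspring)} cannot carry "
                f">= {min_germline_carriers} germline siblings"
            )
    for k in range(counts["parental_germline"]):
        offspring_sorted = sorted(offspring)
        while True:
            picks = {a for a in offspring_sorted if rng.random() < 0.5}
            if len(picks) >= min_germline_carriers:
                break
        carriers = _transmit(pedigree, picks, rng)
        events.append(
            InsertionEvent(
                event_id=f"germline_{k:03d}",
                locus=next(loci_iter),
                family=family,
                origin="parental_germline",
                carrier_animals=frozenset(carriers),
                fraction_by_sample=clonal_fractions(carriers),
            )
        )

    # embryonic mosaic
    sampled = sorted(pedigree.sampled_animals())
    for k in range(counts["embryonic_mosaic"]):
        animal = sampled[int(rng.integers(len(sampled)))]
        if isinstance(mosaic_cell_fraction, (int, float)):
            frac = float(mosaic_cell_fraction)
        else:
            lo, hi = mosaic_cell_fraction
            frac = float(rng.uniform(lo, hi))
        events.append(
            InsertionEvent(
                event_id=f"mosaic_{k:03d}",
                locus=next(loci_iter),
                family=family,
                origin="embryonic_mosaic",
                carrier_animals=frozenset({animal}),
                fraction_by_sample={
                    s: frac for s in pedigree.samples_of(animal)
                },
            )
        )
    return InsertionTruthSet(events=events)
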