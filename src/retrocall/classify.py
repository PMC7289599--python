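"""Pedigree-aware classification of called insertions.

Novel-stream loci are sorted into:

* ``germline`` — called in at least two full siblings of one mating, absent
  from both parents and from every screened animal that is not a descendant
  of those siblings (transmission to the carriers' own offspring is
  allowed): the insertion arose in a parent's germ line.
* ``de_novo`` — called in exactly one animal, with not a single supporting
  read at the locus in any sampled ancestor: an embryonic/somatic event.
* ``ambiguous`` — single-animal calls where an ancestor shows >= 1 read.
* ``inherited_candidate`` — everything else (multi-animal patterns
  consistent with segregating polymorphism).

The germline rule runs before the single-animal novelty filter, otherwise
sibling-shared germline events would be discarded as "present in more than
one animal".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree

CLASS_COLUMNS = ["locus_id", "family_set", "cls", "carriers", "notes"]


def _carriers(calls: pd.DataFrame) -> dict:
    """locus_id -> set of carrier animals (any called sample)."""
    out: dict[str, set] = {}
    for row in calls.itertuples():
        out.setdefault(row.locus_id, set()).add(row.animal_id)
    return out


def _germline_for_locus(
    carriers: set, pedigree: Pedigree, min_siblings: int
) -> tuple[set, str] | None:
    """If the carrier set fits the germline rule, return (sibling carriers,
    note); otherwise None."""
    screened = pedigree.sampled_animals()
    for (sire, dam), offspring in pedigree.matings().items():
        sib_carriers = carriers & set(offspring)
        if len(sib_carriers) < min_siblings:
            continue
        if sire in carriers or dam in carriers:
            continue
        allowed = set(sib_carriers)
        for a in sib_carriers:
            allowed |= pedigree.descendants(a)
        if carriers - allowed:
            continue  # a screened non-descendant carries it
        # all screened non-descendants must be clean — equivalent to the
        # containment above since carriers are screened by construction
        note = f"siblings of mating {sire}x{dam}"
        return sib_carriers, note
    return None


def classify_insertions(
    calls: pd.DataFrame,
    raw_counts: pd.DataFrame,
    pedigree: Pedigree,
    min_siblings: int = 2,
) -> pd.DataFrame:
    """Classify every novel-stream locus.

    Parameters
    ----------
    calls : DataFrame
        Output of :func:`retrocall.caller.call_insertions` (animal_id set
        from the pedigree).
    raw_counts : DataFrame
        Unthresholded per-(locus, sample) anchored-read counts
        (:func:`retrocall.caller.raw_counts_at_loci`); absent rows mean 0.
    pedigree : Pedigree
    min_siblings : int
        Minimum full siblings sharing a locus for the germline rule.

    Returns
    -------
    DataFrame
        locus_id, family_set, cls, carriers (sorted tuple), notes. Classes
        are mutually exclusive per locus.
    """
    novel = calls[calls["stream"] == "novel"]
    for a in novel["animal_id"].unique():
        pedigree.parents(a)  # raises for animals missing from the pedigree
    carriers_by_locus = _carriers(novel)
    fset_of = dict(zip(novel["locus_id"], novel["family_set"]))
    raw = {
        (r.locus_id, r.sample_id): r.count for r in raw_counts.itertuples()
    }
    sampled = pedigree.sampled_animals()

    rows = []
    for locus_id in sorted(carriers_by_locus):
        carriers = carriers_by_locus[locus_id]
        fset = fset_of[locus_id]
        germ = _germline_for_locus(carriers, pedigree, min_siblings)
        if germ is not None:
            sib_carriers, note = germ
            rows.append(
                dict(
                    locus_id=locus_id,
                    family_set=fset,
                    cls="germline",
                    carriers=tuple(sorted(carriers)),
                    notes=note,
                )
            )
            continue
        if len(carriers) == 1:
            (animal,) = carriers
            ancestors = pedigree.ancestors(animal)
            unsampled = ancestors - sampled
            ancestor_reads = 0
            for anc in ancestors & sampled:
                for s in pedigree.samples_of(anc):
                    ancestor_reads += raw.get((locus_id, s), 0)
            if ancestor_reads == 0:
                note = "ancestors read-free"
                if unsampled:
                    note += f"; unsampled ancestors assumed clean: {sorted(unsampled)}"
                rows.append(
                    dict(
                        locus_id=locus_id,
                        family_set=fset,
                        cls="de_novo",
                        carriers=(animal,),
                        notes=note,
                    )
                )
            else:
                rows.append(
                    dict(
                        locus_id=locus_id,
                        family_set=fset,
                        cls="ambiguous",
                        carriers=(animal,),
                        notes=f"{ancestor_reads} supporting reads in ancestors",
                    )
                )
            continue
        rows.append(
            dict(
                locus_id=locus_id,
                family_set=fset,
                cls="inherited_candidate",
                carriers=tuple(sorted(carriers)),
                notes="shared by animals outside the germline rule",
            )
        )
    return pd.DataFrame(rows, columns=CLASS_COLUMNS)


def per_animal_novel_counts(classified: pd.DataFrame, pedigree: Pedigree) -> pd.DataFrame:
    """Per-animal count of de novo insertions (single-animal novel events),
    the pedigree-figure-style summary; germline events counted once per
    carrier."""
    counts = {a: 0 for a in pedigree.animal_ids()}
    for row in classified.itertuples():
        if row.cls in ("de_novo", "germline"):
            for a in row.carriers:
                if a in counts:
                    counts[a] += 1
    return pd.DataFrame(
        {"animal_id": list(counts), "novel_insertions": list(counts.values())}
    )


@dataclass
class SupportStats:
    """Per-class support medians and one-sided rank-sum comparisons."""

    medians: dict
    tests: pd.DataFrame  # comparison, n_less, n_greater, statistic, p_value
    notes: list


def locus_support(calls: pd.DataFrame, classified: pd.DataFrame) -> pd.DataFrame:
    """Per-locus representative support: the maximum per-sample anchored
    read count among the locus's called samples."""
    cls_of = dict(zip(classified["locus_id"], classified["cls"]))
    sub = calls[calls["locus_id"].isin(cls_of)]
    agg = sub.groupby("locus_id")["support"].max().reset_index()
    agg["cls"] = agg["locus_id"].map(cls_of)
    return agg


def compare_support(
    classified: pd.DataFrame,
    calls: pd.DataFrame,
    annotated_flank_support=None,
    min_loci: int = 3,
) -> SupportStats:
    """Compare read support of de novo vs germline (and vs annotated
    reference-element flanks).

    A one-sided Mann–Whitney rank-sum test asks whether de novo loci are
    supported by fewer reads than germline / annotated loci — mosaic
    (embryonic) events are carried by a fraction of cells and should show
    proportionally thinner support.

    ``annotated_flank_support``: optional array of per-locus support values
    at annotated-element flanks (the ``annotated_proximal`` stream).
    """
    per_locus = locus_support(calls, classified)
    groups = {
        cls: per_locus.loc[per_locus["cls"] == cls, "support"].to_numpy()
        for cls in ("de_novo", "germline")
    }
    if annotated_flank_support is not None:
        groups["annotated"] = np.asarray(annotated_flank_support)
    medians = {
        cls: float(np.median(v)) for cls, v in groups.items() if len(v) > 0
    }
    notes = []
    rows = []
    de_novo = groups.get("de_novo", np.array([]))
    for other in ("germline", "annotated"):
        vals = groups.get(other, np.array([]))
        if len(de_novo) < min_loci or len(vals) < min_loci:
            notes.append(
                f"comparison de_novo vs {other} omitted "
                f"(need >= {min_loci} loci per class)"
            )
            continue
        res = stats.mannwhitneyu(de_novo, vals, alternative="less")
        rows.append(
            dict(
                comparison=f"de_novo<{other}",
                n_less=len(de_novo),
                n_greater=len(vals),
                statistic=float(res.statistic),
                p_value=float(res.pvalue),
            )
        )
    tests = pd.DataFrame(
        rows, columns=["comparison", "n_less", "n_greater", "statistic", "p_value"]
    )
    return SupportStats(medians=medians, tests=tests, notes=notes)
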