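"""End-to-end benchmark workflows on synthetic screens.

These functions wire the generators to the calling/classification stages
under the study's default conditions and return the headline quantities:
recall of intact reference elements, specificity on an inherited-only
screen, germline recovery, and the de novo vs germline support contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caller import CallerConfig, compute_recall, run_caller
from .classify import SupportStats, classify_insertions, compare_support
from .simulate import (
    make_pedigree,
    make_reference,
    plant_insertions,
    simulate_capture_reads,
)


def recall_benchmark(
    seed: int = 1,
    n_intact: int = 100,
    n_solo_ltr: int = 100,
    depth: float = 30,
    n_samples: int = 3,
):
    """Recovery of intact reference elements on a clean simulated capture.

    Builds a reference with ``n_intact`` intact elements, simulates
    noise-free capture pairs at ``depth`` fragments per insertion end for
    ``n_samples`` samples, runs the caller at default thresholds, and
    scores per-sample recall within 1 kb of either LTR terminus (before
    the annotation-exclusion step).

    Returns dict with ``median_recall``, ``per_sample`` and ``n_elements``.
    """
    reference = make_reference(
        n_intact=n_intact, n_solo_ltr=n_solo_ltr, families=["ETn"], seed=seed
    )
    samples = [f"s{i + 1}" for i in range(n_samples)]
    pairs = simulate_capture_reads(
        None, reference, samples=samples, depth=depth, noise_rate=0.0, seed=seed + 1
    )
    config = CallerConfig()
    result = run_caller(pairs, reference.annotation, config)
    report = compute_recall(
        result["loci"], result["support"], reference.intact_elements, config
    )
    return dict(
        median_recall=report.median,
        per_sample=report.per_sample,
        n_elements=report.n_elements,
    )


def mulv_specificity_screen(seed: int = 1, n_inherited: int = 5, depth: float = 30):
    """Inherited-only MuLV screen on an 8-animal pedigree.

    Only founder-polymorphic (inherited) MuLV insertions are planted; any
    de novo or germline MuLV classification is a false positive. Returns
    dict with ``n_novel_mulv`` (should be 0), the classification table and
    the truth set.
    """
    pedigree = make_pedigree(n_offspring_g1=6, n_offspring_g2=0)
    assert len(pedigree.animals) == 8
    reference = make_reference(
        n_intact=30, n_solo_ltr=30, families=["MuLV"], seed=seed
    )
    truth = plant_insertions(
        pedigree,
        reference,
        {"founder_polymorphic": n_inherited},
        seed=seed + 1,
        family="MuLV",
    )
    pairs = simulate_capture_reads(
        truth,
        reference,
        samples=list(pedigree.samples["sample_id"]),
        depth=depth,
        noise_rate=0.0,
        seed=seed + 2,
    )
    result = run_caller(pairs, reference.annotation, CallerConfig(), pedigree=pedigree)
    classified = classify_insertions(result["calls"], result["raw_counts"], pedigree)
    mulv = classified[classified["family_set"] == "MuLV"]
    n_novel = int(mulv["cls"].isin(["de_novo", "germline"]).sum())
    return dict(
        n_novel_mulv=n_novel, classified=classified, truth=truth, calls=result["calls"]
    )


def germline_recovery_screen(seed: int = 1, n_germline: int = 3, depth: float = 30):
    """Plant ``n_germline`` parental-germline events (the printed count of
    the screen is three) and recover them with carriers.

    Returns dict with ``n_recovered``, ``carriers_match`` (bool), plus the
    tables.
    """
    pedigree = make_pedigree()
    reference = make_reference(n_intact=20, n_solo_ltr=20, seed=seed)
    truth = plant_insertions(
        pedigree, reference, {"parental_germline": n_germline}, seed=seed + 1
    )
    pairs = simulate_capture_reads(
        truth,
        reference,
        samples=list(pedigree.samples["sample_id"]),
        depth=depth,
        noise_rate=0.0,
        seed=seed + 2,
    )
    result = run_caller(pairs, reference.annotation, CallerConfig(), pedigree=pedigree)
    classified = classify_insertions(result["calls"], result["raw_counts"], pedigree)
    germline = classified[classified["cls"] == "germline"]
    matches = 0
    for event in truth.events:
        hit = [
            row
            for row in germline.itertuples()
            if row.locus_id.split(":")[1] == event.locus.chrom
            and abs(int(row.locus_id.split(":")[2].split("-")[0]) - event.locus.start)
            < 2000
        ]
        if len(hit) == 1 and set(hit[0].carriers) == set(event.carrier_animals):
            matches += 1
    return dict(
        n_recovered=len(germline),
        carriers_match=(matches == len(truth.events)),
        classified=classified,
        truth=truth,
    )


def support_contrast_screen(
    seed: int = 1,
    n_germline: int = 3,
    n_mosaic: int = 6,
    mosaic_cell_fraction: float = 0.15,
    depth: float = 30,
) -> dict:
    """Default fixture for the support comparison: clonal germline events
    vs mosaic events at cell fraction 0.15, one-sided rank-sum test of
    de novo support < germline support."""
    pedigree = make_pedigree()
    reference = make_reference(n_intact=20, n_solo_ltr=20, seed=seed)
    truth = plant_insertions(
        pedigree,
        reference,
        {"parental_germline": n_germline, "embryonic_mosaic": n_mosaic},
        seed=seed + 1,
        mosaic_cell_fraction=mosaic_cell_fraction,
    )
    pairs = simulate_capture_reads(
        truth,
        reference,
        samples=list(pedigree.samples["sample_id"]),
        depth=depth,
        noise_rate=0.0,
        seed=seed + 2,
    )
    result = run_caller(pairs, reference.annotation, CallerConfig(), pedigree=pedigree)
    classified = classify_insertions(result["calls"], result["raw_counts"], pedigree)
    stats = compare_support(classified, result["calls"])
    row = stats.tests[stats.tests["comparison"] == "de_novo<germline"]
    p = float(row.iloc[0]["p_value"]) if len(row) else float("nan")
    return dict(stats=stats, p_value=p, classified=classified, truth=truth)
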