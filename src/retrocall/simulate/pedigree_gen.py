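"""Default multi-generation pedigrees for the insertion screen.

The standard fixture mirrors an ancestry-controlled breeding scheme: a
founder mating producing a first-generation litter, one of whose members
is mated to an unrelated founder to produce a second litter. Every animal
contributes a tail sample; optionally some carry a second tissue so that
tissue-discordant mosaic insertions can be exercised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..pedigree import Pedigree


def make_pedigree(
    n_offspring_g1: int = 6,
    n_offspring_g2: int = 4,
    extra_tissue_every: int = 0,
    genotypes=("KO", "KO/WT", "WT"),
    strain: str = "B6;129",
    seed: int = 0,
) -> Pedigree:
    """Three-generation pedigree: founders F0_M x F0_F -> G1 litter;
    G1_000 x founder F1_F -> G2 litter.

    ``extra_tissue_every``: every k-th animal gets a spleen sample in
    addition to tail (0 disables). Genotypes are assigned round-robin —
    they label animals but carry no simulation semantics.
    """
    rng = np.random.default_rng(seed)
    animals = []

    def add(animal_id, sire, dam, i):
        animals.append(
            dict(
                animal_id=animal_id,
                sire_id=sire,
                dam_id=dam,
                genotype=genotypes[i % len(genotypes)],
                strain=strain,
            )
        )

    add("F0_M", None, None, 0)
    add("F0_F", None, None, 1)
    g1 = [f"G1_{i:03d}" for i in range(n_offspring_g1)]
    for i, a in enumerate(g1):
        add(a, "F0_M", "F0_F", i)
    if n_offspring_g2 > 0:
        add("F1_F", None, None, 2)
        g2 = [f"G2_{i:03d}" for i in range(n_offspring_g2)]
        for i, a in enumerate(g2):
            add(a, g1[0], "F1_F", i)
    animals_df = pd.DataFrame(animals)

    samples = []
    for i, a in enumerate(animals_df["animal_id"]):
        samples.append(
            dict(sample_id=f"{a}-T", animal_id=a, tissue="tail", age_class="juvenile")
        )
        if extra_tissue_every and i % extra_tissue_every == 0:
            samples.append(
                dict(sample_id=f"{a}-S", animal_id=a, tissue="spleen", age_class="adult")
            )
    _ = rng  # reserved for future randomized structures
    return Pedigree(animals_df, pd.DataFrame(samples))
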