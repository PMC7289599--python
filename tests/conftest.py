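import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from retrocall.caller import CallerConfig, run_caller
from retrocall.simulate import (
    make_pedigree,
    make_reference,
    plant_insertions,
    simulate_capture_reads,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_pair(
    sample="s1",
    chrom1="chr1", start1=0, length1=50, strand1="+", unique1=True, dup1=False,
    chrom2="chr1", start2=1000, length2=50, strand2="-", unique2=True, dup2=False,
):
    """One read-pair row for hand-built caller fixtures."""
    return dict(
        sample_id=sample,
        chrom1=chrom1, start1=start1, end1=start1 + length1, strand1=strand1,
        unique1=unique1, dup1=dup1,
        chrom2=chrom2, start2=start2, end2=start2 + length2, strand2=strand2,
        unique2=unique2, dup2=dup2,
    )


def pairs_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_reference():
    return make_reference(n_intact=20, n_solo_ltr=20, seed=11)


@pytest.fixture(scope="session")
def default_pedigree():
    return make_pedigree()


@pytest.fixture(scope="session")
def planted_screen(small_reference, default_pedigree):
    """A full simulated screen: 3 germline + 4 mosaic (cell fraction 0.15)
    events at depth 30, no background noise, with the caller run on it."""
    truth = plant_insertions(
        default_pedigree,
        small_reference,
        {"parental_germline": 3, "embryonic_mosaic": 4},
        seed=7,
        mosaic_cell_fraction=0.15,
    )
    pairs = simulate_capture_reads(
        truth,
        small_reference,
        samples=list(default_pedigree.samples["sample_id"]),
        depth=30,
        noise_rate=0.0,
        seed=8,
    )
    result = run_caller(
        pairs, small_reference.annotation, CallerConfig(), pedigree=default_pedigree
    )
    return dict(
        reference=small_reference,
        pedigree=default_pedigree,
        truth=truth,
        pairs=pairs,
        **result,
    )
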