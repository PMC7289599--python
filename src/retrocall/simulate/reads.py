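"""Capture read-pair simulator.

Emulates a targeted capture of LTR ends: probes tile the first
``probe_len`` bp of the 5' LTR and the last ``probe_len`` bp of the 3' LTR
(both ends of a solitary LTR). Each captured fragment yields one mate
starting inside a probe window (the repeat-side mate) and one mate in
flanking sequence at fragment-length distance (the anchor). Reads are
emitted as already-aligned records; a unique/multimapping boolean stands
in for mapping quality.

For *planted* (non-reference) insertions the repeat-side mate cannot map
to the new element — it maps to an existing annotated copy of the family —
so its coordinates are drawn from a random annotated LTR's probe window,
while the anchor stays at the planted locus. Mosaic events are thinned:
per sample, the fragment count is Poisson(depth x cell fraction) per end,
so the expected support scales with the carried cell fraction and tissues
of one animal acquire partially overlapping insertion sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .insertions import InsertionTruthSet
from .reference import ReferenceBundle

PAIR_COLUMNS = [
    "sample_id",
    "chrom1", "start1", "end1", "strand1", "unique1", "dup1",
    "chrom2", "start2", "end2", "strand2", "unique2", "dup2",
]

#: probability that a mate is reported multimapping (unique=False)
MULTIMAP_RATE_REPEAT = 0.9
MULTIMAP_RATE_FLANK = 0.02


def _truncnorm_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.rvs(size=n, random_state=rng)


class _PairBuilder:
    def __init__(self, rng, read_len, frag_mean, frag_sd, probe_len):
        self.rng = rng
        self.read_len = read_len
        self.frag_mean = frag_mean
        self.frag_sd = frag_sd
        self.probe_len = probe_len
        self.rows: list = []

    def signal_pairs(
        self,
        sample: str,
        n: int,
        probe_chrom: str,
        probe_terminus: int,
        probe_side: str,
        anchor_chrom: str,
        anchor_terminus: int,
        anchor_side: str,
        chrom_sizes: dict,
    ) -> None:
        """Emit ``n`` pairs: repeat mate in the probe window at
        ``probe_terminus`` (side ``left`` = window extends right of the
        terminus, i.e. a 5' LTR start; ``right`` = window extends left,
        a 3' LTR end), anchor mate in the flank beyond
        ``anchor_terminus``."""
        if n <= 0:
            return
        rng = self.rng
        L = self.read_len
        offs = rng.integers(0, self.probe_len - L + 1, size=n)
        frags = _truncnorm_lengths(
            rng, n, self.frag_mean, self.frag_sd, L + 10, 1000
        ).astype(int)
        gaps = np.maximum(frags - 2 * L, 0)
        for i in range(n):
            if probe_side == "left":
                r_start = probe_terminus + int(offs[i])
            else:
                r_start = probe_terminus - int(offs[i]) - L
            if anchor_side == "left":
                a_start = anchor_terminus - int(gaps[i]) - L
            else:
                a_start = anchor_terminus + int(gaps[i])
            a_start = max(0, min(a_start, chrom_sizes[anchor_chrom] - L))
            r_start = max(0, min(r_start, chrom_sizes[probe_chrom] - L))
            uniq_r = rng.random() >= MULTIMAP_RATE_REPEAT
            uniq_a = rng.random() >= MULTIMAP_RATE_FLANK
            repeat_mate = (probe_chrom, r_start, r_start + L,
                           "+" if probe_side == "left" else "-", uniq_r, False)
            anchor_mate = (anchor_chrom, a_start, a_start + L,
                           "+" if anchor_side == "right" else "-", uniq_a, False)
            if rng.random() < 0.5:
                m1, m2 = anchor_mate, repeat_mate
            else:
                m1, m2 = repeat_mate, anchor_mate
            self.rows.append((sample, *m1, *m2))

    def noise_pairs(self, sample: str, n: int, chrom_sizes: dict) -> None:
        if n <= 0:
            return
        rng = self.rng
        chroms = sorted(chrom_sizes)
        L = self.read_len
        for _ in range(n):
            mates = []
            for _m in range(2):
                chrom = chroms[rng.integers(len(chroms))]
                start = int(rng.integers(0, chrom_sizes[chrom] - L))
                strand = "+" if rng.random() < 0.5 else "-"
                uniq = rng.random() >= MULTIMAP_RATE_FLANK
                mates.append((chrom, start, start + L, strand, uniq, False))
            self.rows.append((sample, *mates[0], *mates[1]))


def _element_ends(reference: ReferenceBundle):
    """Probe/anchor geometry of every annotated element of the simulated
    family sets: yields (family_set, chrom, terminus, probe_side)."""
    truth_ids = {t.insertion_id for t in reference.intact_elements}
    for t in reference.intact_elements:
        yield t.family, t.span.chrom, t.ltr5.start, "left"
        yield t.family, t.span.chrom, t.ltr3.end, "right"
    ann = reference.annotation.df
    solo = ann[~ann["insertion_id"].isin(truth_ids)]
    for row in solo.itertuples():
        fam_set = str(row.insertion_id).split("_")[0]
        yield fam_set, row.chrom, row.start, "left"
        yield fam_set, row.chrom, row.end, "right"


def simulate_capture_reads(
    truth: InsertionTruthSet | None,
    reference: ReferenceBundle,
    samples=("s1",),
    depth: float = 30,
    read_len: int = 50,
    frag_mean: float = 350,
    frag_sd: float = 50,
    probe_len: int = 120,
    noise_rate: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate capture read pairs for annotated elements and planted
    insertions.

    Parameters
    ----------
    truth : InsertionTruthSet or None
        Planted events (None = reference elements only).
    samples : iterable of str
        Samples to simulate. For planted events, only samples present in
        an event's ``fraction_by_sample`` receive its reads.
    depth : float
        Expected fragments per insertion end (Poisson); mosaic events are
        thinned to ``depth x cell fraction``.
    noise_rate : float
        Expected uniform background pairs as a fraction of signal pairs.

    Returns
    -------
    DataFrame
        Read-pair table (``PAIR_COLUMNS``), coordinate-sorted by mate 1.
        Zero depth yields an empty table.
    """
    if frag_sd < 0:
        raise ValueError("frag_sd must be >= 0")
    if read_len >= frag_mean:
        raise ValueError("read_len must be < frag_mean")
    ltr_lens = [
        row.end - row.start
        for row in reference.annotation.df.itertuples()
        if row.rep_class == "LTR"
    ]
    if ltr_lens and probe_len > min(ltr_lens):
        raise ValueError(
            f"probe_len {probe_len} exceeds shortest LTR ({min(ltr_lens)} bp)"
        )
    rng = np.random.default_rng(seed)
    builder = _PairBuilder(rng, read_len, frag_mean, frag_sd, probe_len)
    ends = list(_element_ends(reference))

    # probe windows of annotated LTR ends per family set, used as mapped
    # locations for reads from non-reference (planted) elements
    probe_sites: dict[str, list] = {}
    for fam_set, chrom, terminus, side in ends:
        probe_sites.setdefault(fam_set, []).append((chrom, terminus, side))

    n_signal = {s: 0 for s in samples}
    for sample in samples:
        for fam_set, chrom, terminus, side in ends:
            n = int(rng.poisson(depth))
            anchor_side = "left" if side == "left" else "right"
            builder.signal_pairs(
                sample, n, chrom, terminus, side, chrom, terminus, anchor_side,
                reference.chrom_sizes,
            )
            n_signal[sample] += n
        if truth is not None:
            for event in truth.events:
                frac = event.fraction_by_sample.get(sample)
                if frac is None:
                    continue
                sites = probe_sites.get(event.family)
                if not sites:
                    raise ValueError(
                        f"no annotated {event.family} elements to map repeat "
                        "mates of planted insertions onto"
                    )
                for anchor_side in ("left", "right"):
                    n = int(rng.poisson(depth * frac))
                    for _ in range(n):
                        pchrom, pterm, pside = sites[int(rng.integers(len(sites)))]
                        builder.signal_pairs(
                            sample, 1, pchrom, pterm, pside,
                            event.locus.chrom, event.locus.start, anchor_side,
                            reference.chrom_sizes,
                        )
                        n_signal[sample] += 1
        builder.noise_pairs(
            sample, int(rng.poisson(noise_rate * n_signal[sample])), reference.chrom_sizes
        )
    df = pd.DataFrame(builder.rows, columns=PAIR_COLUMNS)
    if df.empty:
        return df
    return df.sort_values(
        ["sample_id", "chrom1", "start1", "chrom2", "start2"]
    ).reset_index(drop=True)
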