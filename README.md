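# retrocall

Tools for screening mice for new retrotransposon insertions from targeted
capture sequencing, and for the statistics that link KRAB zinc-finger
protein (KRAB-ZFP) binding to transposable-element (TE) silencing.

Mouse genomes carry young, mobile TE families — ETn/ETnERV (MusD) and
MuLV/RLTR4 LTR retrotransposons among them — that are kept silent by
KRAB-ZFP clusters recruiting KAP1/SETDB1. When a cluster is deleted, the
question becomes whether these elements actually mobilize in vivo. The
package implements the computational side of that experiment for people
who have aligned capture-seq read pairs (or want fully synthetic
benchmarks): an insertion-site caller with pedigree-aware de novo /
germline classification, plus the peak-enrichment, TSS-proximity,
TE-expression and CpG-methylation statistics used to characterize the
silencing machinery.

## What it computes

**Insertion calling.** Capture probes target the 120-bp outer ends of the
LTRs, so each sequenced fragment pairs a repeat-derived mate with a
uniquely mapping *anchor* in flanking sequence. A mate is repeat-classified
when it overlaps a target-family repeat by ≥ 50% of the read length;
anchors cluster into loci at ≤ 1 kb separation (`bedtools merge -d 1000`
semantics); per-sample support is normalized to reads per million (RPM)
unique repeat-paired reads of the probe set, and a locus is called at

    RPM = 1e6 · support / N_repeat-paired ≥ 10.

Loci within 1 kb of an annotated same-set repeat or on a blocklist of
known polymorphic insertions are kept in a separate annotated-proximal
stream (used for recall and support baselines) rather than discarded.

**Pedigree classification.** A called locus is *germline* when it appears
in ≥ 2 full siblings but neither parent nor any screened non-descendant;
*de novo* when it appears in exactly one animal with zero supporting
reads in every sampled ancestor; otherwise it is an inherited candidate
(or ambiguous when an ancestor shows a stray read). Support of de novo
(embryonic, mosaic) events is contrasted with germline events by
one-sided rank-sum test.

**Enrichment statistics.** ChIP peaks scaled to 200 bp around summits are
tested per repeat family with a right-tailed Fisher's exact test
(≥ 25%-of-peak overlap rule, BH-adjusted jointly); deregulated genes are
tested for TE proximity with a right-tailed binomial test
`P(X ≥ x), X ~ Bin(n, p)` where `p` is the fraction of all genes within
100 kb of the family, BH-adjusted within LTR and LINE classes; TE
expression is counted once per insertion (fragments grouped by repeat ID,
≥ 20/30-read filters) with a documented approximate NB Wald test; and
bisulfite calls are merged into CpG dyads (complementary CG pairs,
≥ 10× coverage in both conditions) and compared per TE group with a
paired t-test.

**Synthetic data.** `retrocall.simulate` generates references with intact
LTR–internal–LTR elements and solitary LTRs, multi-generation pedigrees,
planted insertions (inherited / parental-germline / embryonic-mosaic with
cell fractions), capture read pairs concentrated in probe windows, and
NB / logistic / beta-binomial omics tables — all seeded, all with truth
labels.

## Worked example

```python
from retrocall.simulate import (make_reference, make_pedigree,
                                plant_insertions, simulate_capture_reads)
from retrocall.caller import CallerConfig, run_caller, compute_recall
from retrocall.classify import classify_insertions, compare_support

ref = make_reference(n_intact=50, n_solo_ltr=100, seed=1)
ped = make_pedigree()
truth = plant_insertions(ped, ref, {"founder_polymorphic": 2,
                                    "parental_germline": 3,
                                    "embryonic_mosaic": 6},
                         seed=2, mosaic_cell_fraction=0.15)
pairs = simulate_capture_reads(truth, ref,
                               samples=list(ped.samples["sample_id"]),
                               depth=30, noise_rate=0.0, seed=3)
res = run_caller(pairs, ref.annotation, CallerConfig(), pedigree=ped)
cls = classify_insertions(res["calls"], res["raw_counts"], ped)
print(cls["cls"].value_counts().to_dict())
print(compare_support(cls, res["calls"]).tests)
```

The same workflow is scripted in `analysis/01…03`; on the default seeds it
prints

```
classified: {'de_novo': 6, 'germline': 3, 'inherited_candidate': 2}
per-class median support: {'de_novo': 8.0, 'germline': 70.0, 'annotated': 53.0}
de_novo<germline: rank-sum p = 1.34e-02
```

i.e. all eleven planted events are recovered with their planted classes;
the six mosaic events (15% of cells) are supported by a median of 8
anchored reads versus 70 for clonal germline events — significantly
thinner support, which is the signature separating embryonic from
germ-line retrotransposition. `02_call_insertions.py` additionally
reports a median 100.0% recovery of the 50 intact reference elements.
`analysis/04…06` run the enrichment, expression/proximity and methylation
stages on synthetic fixtures and write their tables under `results/`.

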