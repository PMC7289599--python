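# Methods

`retrocall` implements the bespoke computational stages of a
retrotransposon-mobilization screen in mice: a targeted-capture
insertion-site caller with pedigree-based classification of new events,
and the statistics used to connect KRAB zinc-finger protein (KRAB-ZFP)
binding to transposable-element (TE) silencing — peak–TE-family
enrichment, TSS-proximity enrichment of deregulated genes, TE-level
expression counting, and CpG-dyad methylation comparison. Every stage is
exercised on synthetic data with known ground truth; no external
sequencing data is required.

## Coordinate conventions

All in-memory coordinates are 0-based half-open `[start, end)`. Writers
emit 1-based coordinates only where a named format requires it
(RepeatMasker `.out`, SAM). "Within *d* bp" is closed: a gap of exactly
*d* qualifies, *d* + 1 does not. This applies uniformly to the 1-kb
anchor-merge distance, the 1-kb annotation exclusion, the recall window
and the 100-kb TSS window.

## Insertion caller

Input is a table of aligned read pairs (one row per pair, both mates with
unique-mapping and duplicate flags). The stages:

1. **Duplicate collapse.** Within a sample, pairs with identical
   (chromosome, start, strand) of both mates collapse to one record,
   emulating single-end duplicate removal applied before unique mapping.
2. **Anchor classification.** A mate is *repeat-classified* when it
   overlaps a target-family repeat fragment by at least
   `min_overlap_fraction` (default 0.5) of the read length. Target
   families come in two probe sets — ETn (RLTRETN, MMETn-int, ETnERV-int,
   ETnERV2-int, ETnERV3-int) and MuLV (RLTR4, RLTR4_MM-int, MuLV-int).
   A pair is kept when exactly one mate is repeat-classified and the
   other maps uniquely, is not a duplicate, and is not itself
   repeat-classified; that mate is the *anchor* localizing the junction.
3. **Clustering.** Anchors of one probe set merge into candidate loci
   when separated by at most `merge_distance` (1000 bp), per chromosome,
   across samples jointly — the semantics of `bedtools merge -d 1000`.
   Clustering conserves reads: per-sample anchor counts sum to per-locus
   support.
4. **Normalization.** Per-sample support is scaled to reads per million
   (RPM) of the sample's unique repeat-paired reads *of that probe set*;
   ETn and MuLV denominators are never pooled.
5. **Calling and partition.** A locus is called in a sample at RPM ≥
   `rpm_threshold` (10; a tie is a call — "at least"). Loci within
   `exclusion_distance` (1000 bp) of an annotated repeat of the same
   probe set, or intersecting the blocklist of known polymorphic
   insertion loci, are diverted to an `annotated_proximal` stream rather
   than dropped: those calls feed the recall computation and the
   support-distribution comparison. The remainder is the `novel` stream.

**Recall** is computed before the annotation exclusion (which would by
construction remove every reference element): an intact element counts as
recovered in a sample when a supported locus lies within 1 kb of either
probed terminus (the 5' end of the 5' LTR or the 3' end of the 3' LTR).
"Supported" means RPM at or above the calling threshold; the screen's
recovery claim does not define "high confidence", so the calling
threshold is used.

A scale caveat documented once here: at desk-scale totals (~10⁴
repeat-paired reads per sample) 10 RPM corresponds to less than one read,
so the RPM threshold only separates loci when totals are deep, as they
were in a real screen. The clean fixtures therefore simulate without
background noise; the threshold's boundary behavior is tested directly on
constructed tables.

## Pedigree classification

Novel-stream loci are classified with the germline rule evaluated
*before* the single-animal filter (otherwise sibling-shared germline
events would be discarded as present in more than one animal):

* **germline** — called in ≥ `min_siblings` (2) full siblings (same sire
  and dam) of one mating, absent from both parents, and absent from
  every screened animal that is not a descendant of those siblings;
  transmission to carriers' descendants is allowed.
* **de novo** — called in exactly one animal and zero anchored reads at
  the locus in every sampled tissue of every ancestor (transitive closure
  over both parental lines). Unsampled ancestors are treated as clean,
  with a caveat recorded in the output notes.
* **ambiguous** — single-animal calls with ≥ 1 ancestor read.
* **inherited_candidate** — every other multi-animal pattern.

Classes are mutually exclusive per locus. The support comparison
summarizes each locus by the maximum per-sample anchored-read count among
its called samples and applies a one-sided Mann–Whitney rank-sum test of
de novo < germline (and de novo < annotated-element flank support); the
underlying screen did not name its test, so the standard nonparametric
choice is made here. Embryonic-mosaic events carried by a fraction *f* of
cells have support binomially thinned to *f* times the clonal
expectation, which is what the test detects.

## Peak–TE enrichment

Peaks are standardized to 200-bp windows centered on summits (clipped at
chromosome bounds and flagged), peak sets called against two controls are
intersected (≥ 1 bp), and the most stringent tier (high → medium → low)
with ≥ 50 peaks is selected, falling back with a warning when none
reaches 50. Per repeat family a right-tailed Fisher's exact test is
computed from a 2×2 table: `a` = peaks with ≥ 25% of their length inside
family intervals (the `-f 0.25` convention, measured on the peak), `b` =
remaining peaks, `c` = family intervals not overlapped by any peak, and
`d = genome_size / (mean peak length + mean family interval length) − a −
b − c`, floored at 0 — an explicit emulation of an interval-Fisher
utility whose internal table construction is version-dependent. The
oracle tests therefore target the Fisher computation given a table, not
the table construction. BH adjustment is joint across all
dataset × family cells; the significance callout is adjusted p < 1e-5.
Because Fisher's test is discrete, its attainable size at nominal 0.05
sits at or below 0.05; the calibration test compares the observed
false-positive fraction against both the nominal bound and the exact
attainable size implied by each table's margins.

Mean ChIP signal at peaks is the arithmetic per-base mean of a coverage
track over the 200-bp peaks assigned to each family; families without
peaks are reported missing, not zero.

## TSS-proximity enrichment

A gene is *near* a feature set when any feature edge lies within the
window (default 100 kb) of its TSS — both flanks, strand ignored, closed
boundary (the window's openness is not stated in the source screen;
closed is chosen and documented here). With `p` the fraction of all genes
near the features, the right-tailed binomial test gives
`P(X ≥ x), X ~ Bin(n, p)` for `x` of `n` deregulated genes near. BH
adjustment runs separately within LTR and LINE classes at α = 0.1. The
nearest-edge distance to a feature set equals the distance to the union
of its intervals, so the implementation merges intervals and binary-
searches; the tests check it against a quadratic double loop.
Distance-banded fractions (< 20 kb, 20–50 kb, 50–100 kb) are reported as
an output table; their values depend on the dataset and are not targets.

## TE expression

Counting: a read overlapping ≥ 1 bp of any fragment of an insertion
(fragments grouped by repeat ID) increments that insertion once, never
twice for two fragments of the same insertion. Spliced-read fractional
overlap is approximated by any-overlap counting. A granularity switch
aggregates rows by insertion or by family. Filtering drops rows with
fewer than 20 (two replicates) or 30 (three replicates) reads total
across all samples, and rows whose insertion span overlaps an excluded
region (e.g. the deleted gene cluster); the filters commute and are
idempotent.

The differential stage is deliberately a simple, documented
approximation — median-of-ratios size factors, pooled method-of-moments
negative-binomial dispersion (`Var = μ + αμ²`), and a Wald test on the
log fold change with a 0.5 pseudocount — and is **not** equivalent to a
shrinkage NB GLM. `differential_te` accepts an external results table for
users who fit the model elsewhere; one test cross-checks the direction
and hit overlap against an independent NB engine on a small fixture. On
null simulations the flagged fraction at BH 0.05 averages ≈ 0.04; an
8-fold planted shift at dispersion 0.1 with three replicates is detected
in > 90% of simulations.

## CpG-dyad methylation

A CpG dyad merges the plus-strand C at `i` with the minus-strand C at
`i + 1`; counts sum, the dyad key is the plus-strand coordinate, and a
dyad covered on one strand only keeps that strand's counts. Aggregation
conserves total coverage. Comparison retains dyads with ≥ 10× coverage in
*both* conditions, then runs a paired t-test per TE group over per-dyad
levels (dyad-level pairing; the alternative of averaging per element
first is noted as an open choice in the source and not taken). Groups
with < 2 retained dyads or zero variance of differences report an
undefined (NaN) p-value rather than a number.

## Synthetic data

The generators define the study conditions; their defaults are fixed
once:

* **Reference** (`make_reference`): 10-Mb chromosome, 50 intact elements
  and 100 solitary LTRs per family by default (element geometry: ETn LTR
  320 bp, internal 4.8 kb; MuLV LTR 520 bp, internal 7.2 kb), placed
  ≥ 2 kb apart with bounded retries (failure raises "genome too small").
  Benchmarks that mirror the screen's ~300-element recovery set scale
  `n_intact` to 100.
* **Pedigree** (`make_pedigree`): founders F0_M × F0_F → six G1
  offspring; G1_000 × founder F1_F → four G2 offspring; a tail sample per
  animal, optional second tissue.
* **Planted insertions** (`plant_insertions`): exact per-origin counts.
  Founder-polymorphic events transmit by seeded coin flips at one half
  per offspring of a carrier; parental-germline events seed ≥ 2 siblings
  of one litter (parents' somatic samples clean) and transmit onward;
  embryonic-mosaic events belong to one animal with cell fraction drawn
  uniform on (0.1, 0.3) unless fixed. Event loci keep ≥ 6 kb clearance
  from annotated repeats and each other so the exclusion filter cannot
  absorb them.
* **Capture reads** (`simulate_capture_reads`): fragments per insertion
  end are Poisson(depth), default depth 30, paired 50-bp reads, fragment
  length truncated normal(350, 50) on [read_len + 10, 1000], 120-bp
  probe windows at the probed LTR termini. Repeat-side mates are flagged
  multimapping with probability 0.9, flank mates 0.02. Mosaic events are
  thinned per sample to Poisson(depth × cell fraction), so tissues of one
  animal acquire partially overlapping insertion sets. Repeat mates of
  planted (non-reference) insertions map to probe windows of random
  annotated copies of the family, as they would after alignment. Uniform
  background pairs are emitted at `noise_rate` (default 0.01) times the
  signal count; fixtures described as clean use 0. Target-site
  duplications, PCR errors and nucleotide-level sequence are not
  simulated — the pipeline consumes aligned records, and alignment is out
  of scope.
* **Omics tables** (`simulate_omics_tables`): NB counts (mean 100,
  dispersion 0.1, three replicates per group, planted fold 8); gene/TSS
  tables with logistic upregulation log-odds `b0 + b1·near` (baseline
  ≈ 5% upregulated); beta-binomial methylation (mean 0.8, precision 30,
  coverage Poisson(20) split across strands, planted KO shift on a target
  dyad group).

What passing these tests does *not* show about real data: capture
efficiency biases, mappability structure, strain polymorphism beyond a
static blocklist, PCR duplication structure, or the NB shrinkage behavior
of the published differential engine. The generators are calibrated to
exercise the decision rules, not to reproduce read-level realism.

## Problem sizes and determinism

Every generator takes a single integer seed and is byte-identical across
runs for fixed inputs. Benchmarks use 100 intact elements at depth 30
with 3 samples (recall), an 8-animal pedigree with 5 inherited MuLV
events (specificity), 3 planted germline events (germline recovery), and
3 germline vs 6 mosaic events at cell fraction 0.15 (support contrast);
calibration suites use 100 seeds with 400-gene / 8-family proximity nulls
and 500-peak / 12-family Fisher nulls. These sizes keep any single
benchmark under two minutes on one CPU while leaving the tested
contrasts far from their decision boundaries.
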