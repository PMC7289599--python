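import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats

from retrocall.caller import CallerConfig, run_caller
from retrocall.simulate import (
    OmicsSpec,
    make_pedigree,
    make_reference,
    plant_insertions,
    simulate_capture_reads,
    simulate_gene_tss_table,
    simulate_methylation,
    simulate_te_counts,
)


class TestMakeReference:
    def test_requested_counts_are_exact(self):
        ref = make_reference(n_intact=50, n_solo_ltr=100, families=["ETn"], seed=1)
        assert len(ref.intact_elements) == 50
        solo = ref.annotation.df[
            ref.annotation.df["insertion_id"].str.contains("solo")
        ]
        assert len(solo) == 100
        # intact elements: two LTR fragments flanking one internal fragment
        frag_counts = (
            ref.annotation.df.groupby("insertion_id")["rep_class"]
            .value_counts()
            .unstack(fill_value=0)
        )
        intact_ids = [t.insertion_id for t in ref.intact_elements]
        assert (frag_counts.loc[intact_ids, "LTR"] == 2).all()
        assert (frag_counts.loc[intact_ids, "internal"] == 1).all()

    def test_zero_intact_gives_empty_truth(self):
        ref = make_reference(n_intact=0, n_solo_ltr=5, seed=2)
        assert ref.intact_elements == []

    def test_seeded_determinism(self):
        a = make_reference(n_intact=10, n_solo_ltr=10, seed=7)
        b = make_reference(n_intact=10, n_solo_ltr=10, seed=7)
        assert_frame_equal(a.annotation.df, b.annotation.df)

    def test_elements_within_bounds_and_spaced(self):
        ref = make_reference(n_intact=30, n_solo_ltr=30, seed=3)
        ref.validate()
        spans = ref.annotation.element_spans().sort_values(["chrom", "start"])
        gaps = spans["start"].to_numpy()[1:] - spans["end"].to_numpy()[:-1]
        assert (gaps >= 2000).all()

    def test_too_small_genome_raises(self):
        with pytest.raises((ValueError, RuntimeError)):
            make_reference(chrom_len=60_000, n_intact=50, n_solo_ltr=0, seed=1)


class TestPlantInsertions:
    def test_conservation_of_event_counts(self, default_pedigree, small_reference):
        rates = {"founder_polymorphic": 2, "parental_germline": 3, "embryonic_mosaic": 4}
        truth = plant_insertions(default_pedigree, small_reference, rates, seed=5)
        by = truth.by_origin()
        assert {k: len(v) for k, v in by.items()} == {
            "founder_polymorphic": 2,
            "parental_germline": 3,
            "embryonic_mosaic": 4,
        }

    def test_zero_rates_empty(self, default_pedigree, small_reference):
        truth = plant_insertions(default_pedigree, small_reference, {}, seed=5)
        assert truth.events == []

    def test_germline_events_have_sibling_carriers_and_clean_parents(
        self, default_pedigree, small_reference
    ):
        truth = plant_insertions(
            default_pedigree, small_reference, {"parental_germline": 3}, seed=9
        )
        for e in truth.events:
            litter_carriers = {a for a in e.carrier_animals if a.startswith("G1")}
            assert len(litter_carriers) >= 2
            assert not {"F0_M", "F0_F"} & e.carrier_animals

    def test_germline_without_offspring_errors(self, small_reference):
        ped = make_pedigree(n_offspring_g1=3, n_offspring_g2=0)
        with pytest.raises(ValueError):
            plant_insertions(
                ped,
                small_reference,
                {"parental_germline": 1},
                germline_mating=("G1_000", "G1_001"),
            )

    def test_seeded_determinism(self, default_pedigree, small_reference):
        rates = {"founder_polymorphic": 1, "parental_germline": 2, "embryonic_mosaic": 2}
        a = plant_insertions(default_pedigree, small_reference, rates, seed=13)
        b = plant_insertions(default_pedigree, small_reference, rates, seed=13)
        assert_frame_equal(a.to_frame(), b.to_frame())

    def test_mosaic_support_scales_with_cell_fraction(
        self, default_pedigree, small_reference
    ):
        """Binomial-thinning oracle: a cell fraction f event should show
        about f times the anchored support of a clonal event at the same
        depth (checked within 3 SD of the Poisson means over 20 seeds)."""
        depth, frac, n_seeds = 30.0, 0.2, 20
        mosaic_support = []
        clonal_support = []
        for seed in range(n_seeds):
            for cf, store in ((frac, mosaic_support), (1.0, clonal_support)):
                truth = plant_insertions(
                    default_pedigree,
                    small_reference,
                    {"embryonic_mosaic": 1},
                    seed=100 + seed,
                    mosaic_cell_fraction=cf,
                )
                event = truth.events[0]
                sample = sorted(event.fraction_by_sample)[0]
                pairs = simulate_capture_reads(
                    truth,
                    small_reference,
                    samples=[sample],
                    depth=depth,
                    noise_rate=0.0,
                    seed=200 + seed,
                )
                res = run_caller(pairs, small_reference.annotation, CallerConfig())
                loci = res["loci"]
                near = loci[
                    (loci["chrom"] == event.locus.chrom)
                    & (loci["start"] - 2000 < event.locus.start)
                    & (loci["end"] + 2000 > event.locus.start)
                ]
                sup = res["support"][res["support"]["locus_id"].isin(near["locus_id"])]
                store.append(sup["support"].sum())
        # both ends contribute: clonal mean 2*depth, mosaic mean 2*depth*f
        mean_mosaic = np.mean(mosaic_support)
        expected = 2 * depth * frac
        sd = np.sqrt(expected / n_seeds)
        assert abs(mean_mosaic - expected) <= 3 * sd
        assert np.mean(clonal_support) > 3 * mean_mosaic


class TestSimulateCaptureReads:
    def test_probe_concentration(self, small_reference):
        """Every signal pair has its repeat-side mate starting within the
        120-bp probe window of an LTR terminus."""
        pairs = simulate_capture_reads(
            None, small_reference, samples=["s1"], depth=5, noise_rate=0.0, seed=3
        )
        ann = small_reference.annotation.df
        ltr = ann[ann["rep_class"] == "LTR"]
        termini = []
        for row in ltr.itertuples():
            termini.append((row.chrom, row.start, "left"))
            termini.append((row.chrom, row.end, "right"))
        for r in pairs.itertuples():
            ok = False
            for mate in (1, 2):
                s = getattr(r, f"start{mate}")
                e = getattr(r, f"end{mate}")
                chrom = getattr(r, f"chrom{mate}")
                for tchrom, t, side in termini:
                    if chrom != tchrom:
                        continue
                    if side == "left" and t <= s and e <= t + 120:
                        ok = True
                    if side == "right" and t - 120 <= s and e <= t:
                        ok = True
            assert ok

    def test_depth_zero_or_empty_truth_gives_no_rows(self, default_pedigree):
        empty_ref = make_reference(n_intact=0, n_solo_ltr=0, seed=1)
        pairs = simulate_capture_reads(
            None, empty_ref, samples=["s1"], depth=10, noise_rate=0.0, seed=1
        )
        assert len(pairs) == 0

    def test_clonal_event_well_supported_at_depth_30(
        self, default_pedigree, small_reference
    ):
        """Poisson(30) per insertion end: at least 20 flank-anchored pairs
        at the locus in >= 95% of seeds (here both ends contribute, mean
        60 per sample)."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            truth = plant_insertions(
                default_pedigree,
                small_reference,
                {"embryonic_mosaic": 1},
                seed=300 + seed,
                mosaic_cell_fraction=1.0,
            )
            event = truth.events[0]
            sample = sorted(event.fraction_by_sample)[0]
            pairs = simulate_capture_reads(
                truth, small_reference, samples=[sample],
                depth=30, noise_rate=0.0, seed=400 + seed,
            )
            res = run_caller(pairs, small_reference.annotation, CallerConfig())
            loci = res["loci"]
            near = loci[
                (loci["chrom"] == event.locus.chrom)
                & (loci["start"] - 2000 < event.locus.start)
                & (loci["end"] + 2000 > event.locus.start)
            ]
            sup = res["support"][res["support"]["locus_id"].isin(near["locus_id"])]
            if sup["support"].sum() >= 20:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_negative_frag_sd_errors(self, small_reference):
        with pytest.raises(ValueError):
            simulate_capture_reads(None, small_reference, frag_sd=-1)

    def test_seeded_determinism(self, small_reference):
        a = simulate_capture_reads(
            None, small_reference, samples=["s1"], depth=3, seed=17
        )
        b = simulate_capture_reads(
            None, small_reference, samples=["s1"], depth=3, seed=17
        )
        assert_frame_equal(a, b)


class TestOmicsGenerators:
    def test_null_proximity_effect_leaves_up_fraction_flat(self):
        """With zero proximity effect the upregulated fraction near TEs
        matches the global fraction (3 SD over 50 seeds)."""
        diffs = []
        for seed in range(50):
            genes, features, truth = simulate_gene_tss_table(
                OmicsSpec(proximity_effect=0.0, n_genes=400), seed=seed
            )
            near = truth["near"].to_numpy()
            up = (genes["status"] == "up").to_numpy()
            if near.sum() == 0:
                continue
            diffs.append(up[near].mean() - up.mean())
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) <= 3 * se + 1e-9

    def test_nb_fold_change_matches_planted_effect(self):
        """Planted 4x mean shift: the median simulated fold change across
        seeds stays within a band around 4 (NB sampling oracle)."""
        folds = []
        for seed in range(50):
            table, truth = simulate_te_counts(
                OmicsSpec(n_te=50, n_de=10, nb_mean=100, de_fold=4.0), seed=seed
            )
            de = truth[truth].index
            wt = table.loc[de, [c for c in table if c.startswith("wt")]].mean(axis=1)
            ko = table.loc[de, [c for c in table if c.startswith("ko")]].mean(axis=1)
            folds.append(float((ko / wt).median()))
        assert 3.0 <= np.median(folds) <= 5.3

    def test_beta_binomial_mean_matches_spec(self):
        wt, ko, truth = simulate_methylation(
            OmicsSpec(n_dyads=1000, meth_mean_wt=0.8, meth_coverage=20), seed=4
        )
        per_call = wt["methylated"].sum() / wt["coverage"].sum()
        assert abs(per_call - 0.8) <= 0.05

    def test_nonpositive_dispersion_errors(self):
        with pytest.raises(ValueError):
            OmicsSpec(nb_dispersion=0.0)
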