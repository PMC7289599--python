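import numpy as np
import pandas as pd
import pytest

from retrocall.annotation import RepeatAnnotation
from retrocall.caller import (
    CallerConfig,
    anchor_totals,
    call_insertions,
    classify_reads,
    cluster_anchors,
    compute_recall,
    normalize_support,
    partition_loci,
    run_caller,
)
from retrocall.simulate import make_reference, simulate_capture_reads

from conftest import make_pair, pairs_frame


def tiny_annotation(rows=None):
    """One MMETn-int fragment on chr1 at [10_000, 15_000)."""
    default = [
        dict(chrom="chr1", start=10_000, end=15_000, strand="+",
             family="MMETn-int", rep_class="internal", insertion_id="e1"),
    ]
    return RepeatAnnotation(pd.DataFrame(rows or default))


class TestClassifyReads:
    @pytest.mark.parametrize(
        "overlap_bp,expected_pairs",
        [(25, 1), (24, 0), (50, 1)],
        ids=["half-overlap-kept", "below-half-dropped", "full-overlap-kept"],
    )
    def test_min_overlap_fraction_boundary(self, overlap_bp, expected_pairs):
        """A 50-bp mate needs >= 25 bp inside a target repeat."""
        ann = tiny_annotation()
        # mate2 overlaps the repeat [10000,15000) by overlap_bp at its edge
        pairs = pairs_frame(
            [make_pair(start1=9000, start2=10_000 - (50 - overlap_bp))]
        )
        anchors = classify_reads(pairs, ann, CallerConfig())
        assert len(anchors) == expected_pairs
        if expected_pairs:
            assert anchors.iloc[0]["mate_family"] == "MMETn-int"
            assert anchors.iloc[0]["family_set"] == "ETn"
            assert anchors.iloc[0]["start"] == 9000

    def test_both_mates_repeat_classified_dropped(self):
        ann = tiny_annotation()
        pairs = pairs_frame([make_pair(start1=11_000, start2=12_000)])
        assert len(classify_reads(pairs, ann, CallerConfig())) == 0

    def test_non_unique_anchor_dropped(self):
        ann = tiny_annotation()
        pairs = pairs_frame([make_pair(start1=9000, start2=11_000, unique1=False)])
        assert len(classify_reads(pairs, ann, CallerConfig())) == 0

    def test_duplicates_collapse(self):
        ann = tiny_annotation()
        rows = [make_pair(start1=9000, start2=11_000) for _ in range(3)]
        anchors = classify_reads(pairs_frame(rows), ann, CallerConfig())
        assert len(anchors) == 1

    def test_unknown_chromosome_skipped(self, caplog):
        ann = tiny_annotation()
        pairs = pairs_frame(
            [
                make_pair(start1=9000, start2=11_000),
                make_pair(chrom1="chrUn", start1=9000, start2=11_000),
            ]
        )
        with caplog.at_level("WARNING"):
            anchors = classify_reads(pairs, ann, CallerConfig())
        assert len(anchors) == 1

    def test_non_target_family_ignored(self):
        ann = tiny_annotation(
            [
                dict(chrom="chr1", start=10_000, end=15_000, strand="+",
                     family="L1Md", rep_class="other", insertion_id="l1"),
            ]
        )
        pairs = pairs_frame([make_pair(start1=9000, start2=11_000)])
        assert len(classify_reads(pairs, ann, CallerConfig())) == 0


def anchors_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "strand", "family_set", "mate_family"],
    )


class TestClusterAnchors:
    def make(self, gap):
        return anchors_frame(
            [
                ("s1", "chr1", 1000, 1050, "+", "ETn", "MMETn-int"),
                ("s1", "chr1", 1050 + gap, 1100 + gap, "+", "ETn", "MMETn-int"),
            ]
        )

    def test_merge_distance_boundary(self):
        """Gap of exactly 1000 bp merges; 1001 does not."""
        config = CallerConfig()
        loci, _ = cluster_anchors(self.make(1000), config)
        assert len(loci) == 1
        loci, _ = cluster_anchors(self.make(1001), config)
        assert len(loci) == 2

    def test_single_anchor_single_locus(self):
        loci, support = cluster_anchors(self.make(1000).iloc[:1], CallerConfig())
        assert len(loci) == 1
        assert support["support"].tolist() == [1]

    def test_families_cluster_separately_samples_jointly(self):
        anchors = anchors_frame(
            [
                ("s1", "chr1", 1000, 1050, "+", "ETn", "MMETn-int"),
                ("s2", "chr1", 1200, 1250, "+", "ETn", "RLTRETN"),
                ("s1", "chr1", 1100, 1150, "+", "MuLV", "RLTR4"),
            ]
        )
        loci, support = cluster_anchors(anchors, CallerConfig())
        assert len(loci) == 2  # one ETn locus (both samples), one MuLV
        etn = loci[loci["family_set"] == "ETn"].iloc[0]
        sup = support[support["locus_id"] == etn["locus_id"]]
        assert set(sup["sample_id"]) == {"s1", "s2"}

    def test_clustering_conserves_reads(self, planted_screen):
        anchors, support = planted_screen["anchors"], planted_screen["support"]
        per_sample_anchors = anchors.groupby("sample_id").size().sort_index()
        per_sample_support = (
            support.groupby("sample_id")["support"].sum().sort_index()
        )
        assert per_sample_anchors.equals(per_sample_support)

    def test_idempotence(self):
        """Re-clustering the merged loci changes nothing."""
        config = CallerConfig()
        anchors = anchors_frame(
            [
                ("s1", "chr1", 1000, 1050, "+", "ETn", "MMETn-int"),
                ("s1", "chr1", 1900, 1950, "+", "ETn", "MMETn-int"),
                ("s1", "chr1", 4000, 4050, "+", "ETn", "MMETn-int"),
            ]
        )
        loci1, _ = cluster_anchors(anchors, config)
        again = loci1.rename(columns={})[["chrom", "start", "end", "family_set"]]
        again = again.assign(
            sample_id="s1", strand="+", mate_family="MMETn-int"
        )[["sample_id", "chrom", "start", "end", "strand", "family_set", "mate_family"]]
        loci2, _ = cluster_anchors(again, config)
        assert loci1[["chrom", "start", "end"]].equals(loci2[["chrom", "start", "end"]])


class TestNormalizeSupport:
    def test_rpm_arithmetic(self):
        loci = pd.DataFrame(
            [dict(locus_id="L1", chrom="chr1", start=0, end=100, family_set="ETn")]
        )
        support = pd.DataFrame([dict(locus_id="L1", sample_id="s1", support=30)])
        totals = pd.Series({("s1", "ETn"): 2_000_000})
        out = normalize_support(support, loci, totals)
        assert out["rpm"].tolist() == [15.0]

    def test_scale_invariance(self):
        loci = pd.DataFrame(
            [dict(locus_id="L1", chrom="chr1", start=0, end=100, family_set="ETn")]
        )
        support = pd.DataFrame([dict(locus_id="L1", sample_id="s1", support=7)])
        r1 = normalize_support(support, loci, pd.Series({("s1", "ETn"): 1000}))
        support2 = support.assign(support=14)
        r2 = normalize_support(support2, loci, pd.Series({("s1", "ETn"): 2000}))
        assert r1["rpm"].tolist() == r2["rpm"].tolist()

    def test_missing_total_names_sample(self):
        loci = pd.DataFrame(
            [dict(locus_id="L1", chrom="chr1", start=0, end=100, family_set="ETn")]
        )
        support = pd.DataFrame([dict(locus_id="L1", sample_id="s9", support=1)])
        with pytest.raises(ValueError, match="s9"):
            normalize_support(support, loci, pd.Series(dtype=float))


class TestCallInsertions:
    def setup_tables(self, rpm_values, locus_start=500_000):
        loci = pd.DataFrame(
            [
                dict(
                    locus_id=f"L{i}", chrom="chr1",
                    start=locus_start + 10_000 * i,
                    end=locus_start + 10_000 * i + 500,
                    family_set="ETn",
                )
                for i in range(len(rpm_values))
            ]
        )
        support = pd.DataFrame(
            [
                dict(locus_id=f"L{i}", sample_id="s1", support=int(r * 10), rpm=r)
                for i, r in enumerate(rpm_values)
            ]
        )
        return loci, support

    def test_rpm_threshold_boundary(self):
        """9.9 RPM is not called; 10.0 RPM is ("at least 10")."""
        ann = tiny_annotation()
        loci, support = self.setup_tables([9.9, 10.0])
        calls = call_insertions(loci, support, ann, CallerConfig())
        assert calls["locus_id"].tolist() == ["L1"]

    def test_threshold_monotonicity(self):
        ann = tiny_annotation()
        loci, support = self.setup_tables([5.0, 10.0, 12.0, 50.0])
        lo = call_insertions(loci, support, ann, CallerConfig())
        hi = call_insertions(loci, support, ann, CallerConfig(rpm_threshold=20.0))
        assert set(hi["locus_id"]) <= set(lo["locus_id"])

    @pytest.mark.parametrize(
        "locus_start,stream",
        [
            (15_400, "annotated_proximal"),  # 400 bp gap to repeat end
            (16_000, "annotated_proximal"),  # exactly 1000 bp gap
            (16_001, "novel"),  # 1001 bp gap
        ],
        ids=["400bp", "1000bp-boundary", "1001bp-outside"],
    )
    def test_annotation_exclusion_distance(self, locus_start, stream):
        ann = tiny_annotation()  # repeat ends at 15_000
        loci = pd.DataFrame(
            [dict(locus_id="L0", chrom="chr1", start=locus_start,
                  end=locus_start + 200, family_set="ETn")]
        )
        support = pd.DataFrame(
            [dict(locus_id="L0", sample_id="s1", support=100, rpm=100.0)]
        )
        calls = call_insertions(loci, support, ann, CallerConfig())
        assert calls["stream"].tolist() == [stream]

    def test_blocklist_exclusion(self):
        ann = tiny_annotation()
        block = pd.DataFrame([dict(chrom="chr1", start=499_900, end=500_100)])
        loci, support = self.setup_tables([50.0])
        calls = call_insertions(
            loci, support, ann, CallerConfig(blocklist=block)
        )
        assert calls["stream"].tolist() == ["annotated_proximal"]

    def test_exclusion_is_per_family_set(self):
        """A MuLV locus near an ETn repeat stays novel."""
        ann = tiny_annotation()
        loci = pd.DataFrame(
            [dict(locus_id="L0", chrom="chr1", start=15_400, end=15_600,
                  family_set="MuLV")]
        )
        support = pd.DataFrame(
            [dict(locus_id="L0", sample_id="s1", support=100, rpm=100.0)]
        )
        calls = call_insertions(loci, support, ann, CallerConfig())
        assert calls["stream"].tolist() == ["novel"]


class TestRecall:
    def test_all_elements_flanked_gives_recall_one(self, planted_screen):
        report = compute_recall(
            planted_screen["loci"],
            planted_screen["support"],
            planted_screen["reference"].intact_elements,
            CallerConfig(),
        )
        assert report.median == 1.0

    def test_zero_depth_gives_zero_recall(self, small_reference):
        pairs = simulate_capture_reads(
            None, small_reference, samples=["s1"], depth=0, noise_rate=0.0, seed=1
        )
        assert len(pairs) == 0
        loci = pd.DataFrame(columns=["locus_id", "chrom", "start", "end", "family_set"])
        support = pd.DataFrame(columns=["locus_id", "sample_id", "support", "rpm"])
        report = compute_recall(
            loci, support, small_reference.intact_elements, CallerConfig()
        )
        assert report.median == 0.0

    def test_empty_truth_errors(self, planted_screen):
        with pytest.raises(ValueError):
            compute_recall(
                planted_screen["loci"], planted_screen["support"], [], CallerConfig()
            )


class TestSpecificity:
    def test_no_planted_events_gives_empty_novel_stream(self, small_reference):
        """Reference-only reads: every locus sits at an annotated element
        and lands in the annotated_proximal stream."""
        pairs = simulate_capture_reads(
            None, small_reference, samples=["s1", "s2"], depth=20,
            noise_rate=0.0, seed=21,
        )
        res = run_caller(pairs, small_reference.annotation, CallerConfig())
        assert (res["calls"]["stream"] == "annotated_proximal").all()
        assert len(res["calls"]) > 0
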