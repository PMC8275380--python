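"""Consensus construction, read counting, annotation and variant overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from atacgrn.consensus import (
    Gene,
    GeneModel,
    annotate_peak,
    count_reads,
    cross_sample_consensus,
    intersect_variants,
    reciprocal_overlap,
    replicate_consensus,
)
from atacgrn.intervals import GenomicInterval as GI
from atacgrn.intervals import interval_from_name, merge_intervals

from conftest import brute_force_consensus, random_interval_sets

intervals_st = st.tuples(
    st.integers(0, 900), st.integers(1, 100)
).map(lambda t: GI("chrT", t[0], t[0] + t[1]))


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (GI("c", 0, 100), GI("c", 0, 100), (1.0, 1.0)),
            (GI("c", 0, 100), GI("c", 50, 150), (0.5, 0.5)),
            (GI("c", 0, 100), GI("c", 80, 90), (0.1, 1.0)),
            (GI("c", 0, 100), GI("d", 0, 100), (0.0, 0.0)),
        ],
    )
    def test_fraction_arithmetic(self, a, b, expected):
        assert reciprocal_overlap(a, b) == pytest.approx(expected)

    @given(intervals_st, intervals_st)
    def test_swap_symmetry(self, a, b):
        fa, fb = reciprocal_overlap(a, b)
        fb2, fa2 = reciprocal_overlap(b, a)
        assert (fa, fb) == (fa2, fb2)
        assert 0 <= fa <= 1 and 0 <= fb <= 1

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GI("c", 10, 10)


class TestReplicateConsensus:
    def test_worked_three_replicate_example(self):
        out = replicate_consensus(
            [[GI("c", 0, 100)], [GI("c", 10, 110)], [GI("c", 500, 600)]]
        )
        assert out == [GI("c", 10, 100)]

    def test_identical_replicates_pass_through(self):
        peaks = [GI("c", 5, 50), GI("c", 100, 160)]
        assert replicate_consensus([peaks, peaks, peaks]) == peaks

    def test_half_overlap_fails_reciprocal_criterion(self):
        out = replicate_consensus([[GI("c", 0, 100)], [GI("c", 50, 150)]])
        assert out == []

    def test_exact_75_percent_boundary(self):
        # overlap 75 of 100 on both sides: exactly at the threshold, kept
        out = replicate_consensus([[GI("c", 0, 100)], [GI("c", 25, 125)]])
        assert out == [GI("c", 25, 100)]
        # one base less fails
        out = replicate_consensus([[GI("c", 0, 100)], [GI("c", 26, 126)]])
        assert out == []

    def test_min_replicates_exceeding_input_rejected(self):
        with pytest.raises(ValueError):
            replicate_consensus([[GI("c", 0, 10)]], min_replicates=2)
        with pytest.raises(ValueError):
            replicate_consensus([[], []])

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        for _ in range(40):
            reps = random_interval_sets(rng, int(rng.integers(2, 5)))
            if all(len(r) == 0 for r in reps):
                continue
            got = replicate_consensus(reps, 2, 0.75)
            selected = _oracle_select(reps, 2, 0.75)
            expected = brute_force_consensus(selected, min_support=2)
            assert got == expected

    def test_idempotent_on_own_output(self, rng):
        reps = random_interval_sets(rng, 3)
        if all(len(r) == 0 for r in reps):
            pytest.skip("degenerate draw")
        out = replicate_consensus(reps)
        if out:
            assert replicate_consensus([out, out, out]) == out


def _oracle_select(replicates, min_replicates, min_reciprocal):
    selected = []
    for i, peaks in enumerate(replicates):
        keep = []
        for p in peaks:
            partners = sum(
                any(
                    min(reciprocal_overlap(p, q)) >= min_reciprocal
                    for q in other
                )
                for j, other in enumerate(replicates)
                if j != i
            )
            if partners >= min_replicates - 1:
                keep.append(p)
        selected.append(keep)
    return selected


class TestCrossSampleConsensus:
    def test_support_counting(self):
        samples = [[GI("c", 10, 100)]] * 5 + [[GI("c", 200, 240)]] * 3 + [[]] * 2
        assert cross_sample_consensus(samples, min_samples=4) == [GI("c", 10, 100)]

    def test_support_boundary_three_vs_four(self):
        samples = [[GI("c", 10, 100)]] * 4 + [[]] * 4
        assert cross_sample_consensus(samples, min_samples=4) == [GI("c", 10, 100)]
        samples = [[GI("c", 10, 100)]] * 3 + [[]] * 5
        assert cross_sample_consensus(samples, min_samples=4) == []

    def test_merge_within_42_bases(self):
        samples = [[GI("c", 10, 100), GI("c", 120, 160)]] * 4
        assert cross_sample_consensus(samples, 4, 42) == [GI("c", 10, 160)]

    def test_gap_exactly_43_not_merged(self):
        samples = [[GI("c", 10, 100), GI("c", 143, 160)]] * 4
        assert cross_sample_consensus(samples, 4, 42) == [
            GI("c", 10, 100),
            GI("c", 143, 160),
        ]
        samples = [[GI("c", 10, 100), GI("c", 142, 160)]] * 4
        assert cross_sample_consensus(samples, 4, 42) == [GI("c", 10, 160)]

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        for _ in range(40):
            samples = random_interval_sets(rng, int(rng.integers(4, 9)))
            min_samples = int(rng.integers(1, 5))
            got = cross_sample_consensus(samples, min_samples, 42)
            expected = brute_force_consensus(samples, min_samples, max_gap=42)
            assert got == expected

    def test_monotone_in_min_samples_and_merge_distance(self, rng):
        for _ in range(10):
            samples = random_interval_sets(rng, 6)
            strict = cross_sample_consensus(samples, 4, 42)
            loose = cross_sample_consensus(samples, 3, 42)
            # every strict region is contained in some loose region
            for iv in strict:
                assert any(
                    o.chrom == iv.chrom and o.start <= iv.start and iv.end <= o.end
                    for o in loose
                )
            merged_more = cross_sample_consensus(samples, 4, 100)
            assert len(merged_more) <= len(strict)

    def test_idempotent_on_own_output(self, rng):
        samples = random_interval_sets(rng, 6)
        out = cross_sample_consensus(samples, 4, 42)
        if out:
            assert cross_sample_consensus([out] * 4, 4, 42) == out

    def test_zero_min_samples_rejected(self):
        with pytest.raises(ValueError):
            cross_sample_consensus([[GI("c", 0, 10)]], min_samples=0)


class TestCountReads:
    FEATURES = [GI("c", 21, 200), GI("c", 300, 400)]

    def test_half_overlap_boundary(self):
        counts = count_reads({"s": [GI("c", 0, 42)]}, self.FEATURES)
        assert counts.loc["c:21-200", "s"] == 1  # overlap 21 = half of 42

    def test_one_base_below_half_unassigned(self):
        counts = count_reads({"s": [GI("c", 0, 42)]}, [GI("c", 22, 200)])
        assert counts["s"].sum() == 0  # overlap 20 < 21

    def test_read_inside_feature_assigned(self):
        counts = count_reads({"s": [GI("c", 320, 362)]}, self.FEATURES)
        assert counts.loc["c:300-400", "s"] == 1

    def test_column_sums_invariant_under_feature_reordering(self, rng):
        reads = {
            "s1": [GI("c", int(p), int(p) + 42) for p in rng.integers(0, 380, 200)],
        }
        a = count_reads(reads, self.FEATURES)
        b = count_reads(reads, self.FEATURES[::-1])
        assert a["s1"].sum() == b["s1"].sum()
        assert a.sort_index().equals(b.sort_index())

    def test_each_read_counts_at_most_once(self):
        # read straddles exactly half/half over two bookended features
        feats = [GI("c", 0, 21), GI("c", 21, 42)]
        counts = count_reads({"s": [GI("c", 0, 42)]}, feats)
        assert counts["s"].sum() == 1

    def test_overlapping_features_rejected(self):
        with pytest.raises(ValueError):
            count_reads({"s": []}, [GI("c", 0, 100), GI("c", 50, 150)])


class TestAnnotation:
    MODEL = GeneModel(
        [
            Gene("geneA", "c", 5000, 9000, "+", exons=((5000, 5400), (6500, 7000))),
            Gene("geneB", "c", 40_000, 45_000, "+"),
        ]
    )

    def test_promoter_upstream_of_tss(self):
        peak = GI("c", 4700, 4900)  # midpoint 4800, 200 bp upstream of TSS 5000
        a = annotate_peak(peak, self.MODEL)
        assert (a.category, a.gene) == ("promoter-TSS", "geneA")
        assert a.distance_to_tss == -200

    def test_far_peak_is_intergenic_without_gene(self):
        a = annotate_peak(GI("c", 90_000, 90_200), self.MODEL)
        assert (a.category, a.gene) == ("intergenic", None)

    def test_midpoint_in_exon(self):
        a = annotate_peak(GI("c", 6500, 6900), self.MODEL)  # midpoint 6700
        assert a.category == "exon"

    def test_midpoint_in_intron(self):
        a = annotate_peak(GI("c", 7300, 7700), self.MODEL)  # midpoint 7500
        assert a.category == "intron"

    def test_tts_window(self):
        a = annotate_peak(GI("c", 44_800, 45_000), self.MODEL)
        assert a.category == "TTS"

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            annotate_peak(GI("c", 0, 10), GeneModel([]))

    def test_gene_model_io_roundtrip(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("c\t5000\t9000\tgeneA\t0\t+\nc\t40000\t45000\tgeneB\t0\t-\n")
        model = GeneModel.from_bed6(bed)
        assert [g.name for g in model.genes] == ["geneA", "geneB"]
        assert model.genes[1].tss == 44_999  # minus strand

        gff = tmp_path / "genes.gff"
        gff.write_text(
            "##gff-version 3\n"
            "c\tsrc\tgene\t5001\t9000\t.\t+\t.\tID=geneA\n"
            "c\tsrc\texon\t5001\t5400\t.\t+\t.\tParent=geneA\n"
        )
        model2 = GeneModel.from_gff(gff)
        assert model2.genes[0].start == 5000 and model2.genes[0].exons == ((5000, 5400),)


class TestIntersectVariants:
    PEAKS = [GI("c", 10, 100), GI("c", 200, 260)]

    def test_variant_inside_peak_mapped(self):
        assert intersect_variants([("c", 50)], self.PEAKS)[("c", 50)] == GI("c", 10, 100)

    def test_half_open_end_excluded(self):
        assert ("c", 100) not in intersect_variants([("c", 100)], self.PEAKS)
        assert ("c", 10) in intersect_variants([("c", 10)], self.PEAKS)

    def test_counts_match_brute_force_scan(self, rng):
        peaks = merge_intervals(random_interval_sets(rng, 1, 25)[0])
        variants = [("chrT", int(p)) for p in rng.integers(0, 1000, 110)]
        got = intersect_variants(variants, peaks)
        expected = {
            v: next(iv for iv in peaks if iv.contains_point(*v))
            for v in set(variants)
            if any(iv.contains_point(*v) for iv in peaks)
        }
        assert got == expected


def test_interval_name_roundtrip():
    iv = GI("chrS", 120, 480)
    assert interval_from_name(iv.name) == iv
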