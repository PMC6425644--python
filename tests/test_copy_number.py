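from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import predict_single_bruteforce, random_single_alignment_case, round_to_unit_bruteforce
from repeatlens.annotations import RepeatAnnotation
from repeatlens.copy_number import (
    GAVE_UP,
    NO_COVERAGE,
    PREDICTED,
    PredictionConfig,
    far_near,
    filter_alignments,
    join_colinear,
    net_deletion,
    predict_multi,
    predict_repeat,
    predict_single,
    prepare_read,
    round_to_unit,
)
from repeatlens.maf_io import AlignmentPart, ScoringParams, alignment_gaps, read_maf
from repeatlens.synthetic import ReadSpec, edit_script_to_maf, make_read
from test_maf_io import make_part

from conftest import build_locus


class TestFarNear:
    def test_small_unit(self):
        assert far_near(3, (10_000, 10_000)) == (100, 100, 60)

    def test_large_unit_dominates(self):
        assert far_near(200, (10_000, 10_000)) == (200, 200, 200)

    def test_truncated_at_sequence_edge(self):
        # only 10 bases upstream: the required left extension collapses to 10
        f_left, f_right, n = far_near(3, (10, 10_000))
        assert (f_left, f_right, n) == (10, 100, 60)


class TestRoundToUnit:
    @pytest.mark.parametrize("D,u,expected", [
        (7, 3, 6),
        (9, 6, 6),      # tie 6 vs 12 -> toward zero
        (-9, 6, -6),    # tie on the negative side
        (8, 3, 9),
        (0, 5, 0),
        (-147, 3, -147),
    ])
    def test_examples(self, D, u, expected):
        assert round_to_unit(D, u) == expected

    @given(st.integers(-500, 500), st.integers(1, 12))
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, D, u):
        assert round_to_unit(D, u) == round_to_unit_bruteforce(D, u)


class TestNetDeletion:
    @pytest.mark.parametrize("d,i,r,expected", [
        (0, 147, 0, -147),
        (50, 0, 40, 40),
        (10, 10, 10, 0),
    ])
    def test_examples(self, d, i, r, expected):
        assert net_deletion(d, i, r) == expected


class TestFilterAlignments:
    def test_mismap_cutoff_is_strict(self, config):
        keep = make_part("A" * 60, "A" * 60)
        keep.mismap = 1e-6
        drop = make_part("A" * 60, "A" * 60)
        drop.mismap = 1e-5
        assert filter_alignments([keep, drop], config) == [keep]

    def test_all_lowercase_removed(self, config):
        part = make_part("a" * 100, "a" * 100)
        assert filter_alignments([part], config) == []

    def test_empty(self, config):
        assert filter_alignments([], config) == []


def part_at(ref_start, ref_end, read_start, read_end, strand="+", name="r"):
    n = ref_end - ref_start
    assert n == read_end - read_start
    return AlignmentPart(
        readName=name, readStrand=strand, refName="chr1",
        refStart=ref_start, refEnd=ref_end, refSrcSize=10 ** 7,
        readStart=read_start, readEnd=read_end, readSrcSize=10 ** 6,
        refText="A" * n, readText="A" * n,
    )


class TestJoinColinear:
    def test_bridge_becomes_gap_run(self, config):
        a = part_at(0, 100, 0, 100)
        b = part_at(600, 700, 450, 550)  # ref gap 500, read gap 350
        (merged,) = join_colinear([a, b], config)
        (gap,) = alignment_gaps(merged)
        assert (gap.d, gap.i) == (500, 350)
        assert (merged.refStart, merged.refEnd) == (0, 700)
        assert (merged.readStart, merged.readEnd) == (0, 550)

    def test_large_ref_gap_not_merged(self, config):
        a = part_at(0, 100, 0, 100)
        b = part_at(2_100_100, 2_100_200, 450, 550)
        assert len(join_colinear([a, b], config)) == 2

    def test_opposite_strands_not_merged(self, config):
        a = part_at(0, 100, 0, 100, strand="+")
        b = part_at(600, 700, 450, 550, strand="-")
        assert len(join_colinear([a, b], config)) == 2

    def test_reverse_strand_colinearity(self, config):
        # '-' strand: later read positions map to earlier reference positions
        a = part_at(600, 700, 0, 100, strand="-")
        b = part_at(0, 100, 450, 550, strand="-")
        (merged,) = join_colinear([a, b], config)
        assert (merged.refStart, merged.refEnd) == (0, 700)
        (gap,) = alignment_gaps(merged)
        assert (gap.d, gap.i) == (500, 350)

    def test_transitive_three_way_merge(self, config):
        parts = [part_at(0, 100, 0, 100), part_at(150, 250, 120, 220),
                 part_at(300, 400, 240, 340)]
        (merged,) = join_colinear(parts, config)
        assert (merged.refStart, merged.refEnd) == (0, 400)
        assert len(alignment_gaps(merged)) == 2

    def test_ref_overlap_not_merged(self, config):
        a = part_at(0, 100, 0, 100)
        b = part_at(90, 190, 120, 220)
        assert len(join_colinear([a, b], config)) == 2


def single_part_case(gap_spec, repeat=(300, 360), u=3, span=(100, 600)):
    """Build an alignment over [span) with one gap described by gap_spec:
    (ref position, d, i)."""
    pos, d, i = gap_spec
    s, e = span
    left = pos - s
    ref = "A" * left + "C" * d + "-" * i + "A" * (e - pos - d)
    read = "A" * left + "-" * d + "G" * i + "A" * (e - pos - d)
    part = make_part(ref, read, ref_start=s)
    return part, RepeatAnnotation("chr1", repeat[0], repeat[1], "CAG")


class TestPredictSingle:
    def test_expansion_inside_repeat(self):
        # CAG x 21 repeat, +147 inserted bases -> +49 copies
        part, rep = single_part_case((330, 0, 147), repeat=(300, 363))
        pred = predict_single(part, rep, 100, 100, 60)
        assert (pred.status, pred.copyChange) == (PREDICTED, 49)

    def test_no_gaps_is_zero_change(self):
        part, rep = single_part_case((330, 0, 0))
        # gapless: remove degenerate gap by using d=i=0 -> no gap columns
        part = make_part("A" * 500, "A" * 500, ref_start=100)
        pred = predict_single(part, rep, 100, 100, 60)
        assert (pred.status, pred.copyChange) == (PREDICTED, 0)

    def test_insufficient_extension_gives_up(self):
        part = make_part("A" * 500, "A" * 500, ref_start=250)
        rep = RepeatAnnotation("chr1", 300, 360, "CAG")
        pred = predict_single(part, rep, 100, 100, 60)
        assert pred.status == GAVE_UP

    def test_gap_partly_beyond_f_gives_up(self):
        # gap run straddling the f boundary left of the repeat (positions
        # 150..249, distances 149..50 vs f=100), with enough inserted bases
        # to escape the small-gap rule
        part, rep = single_part_case((150, 100, 5))
        pred = predict_single(part, rep, 100, 100, 60)
        assert pred.status == GAVE_UP

    def test_rule_order_small_gap_beats_partly_far(self):
        # same straddling deletion but with i=1 <= u/2: the small-gap rule
        # fires first and IGNORES it; applying the partly-far rule first
        # would give up instead — the order is semantic
        part, rep = single_part_case((150, 100, 1))
        pred = predict_single(part, rep, 100, 100, 60)
        assert (pred.status, pred.copyChange) == (PREDICTED, 0)

    def test_gap_wholly_beyond_f_ignored(self):
        part, rep = single_part_case((120, 50, 0))  # dists 129..80? no: 179..130
        # positions 120..169, nearest distance 300-170=130 >= f -> ignored
        pred = predict_single(part, rep, 100, 100, 60)
        assert (pred.status, pred.copyChange) == (PREDICTED, 0)

    def test_small_insertion_outside_repeat_ignored_first(self):
        # rule order regression: a 1-base insertion 80 bases left of the
        # repeat is ignored by the small-gap rule even though it is between
        # n and f where later rules would not ignore it
        part, rep = single_part_case((220, 0, 1))
        pred = predict_single(part, rep, 100, 100, 60)
        assert (pred.status, pred.copyChange) == (PREDICTED, 0)

    def test_insertion_near_repeat_counts(self):
        # a 30-base insertion 10 bases left of the repeat: within n, r=0,
        # D=-30 -> +10 copies
        part, rep = single_part_case((290, 0, 30))
        pred = predict_single(part, rep, 100, 100, 60)
        assert (pred.status, pred.copyChange) == (PREDICTED, 10)

    def test_deletion_capped_by_repeat_overlap(self):
        # deletion covering the last 30 repeat bases and 30 flank bases:
        # d=60, r=30 -> D=min(60, 30)=30 -> -10 copies
        part, rep = single_part_case((330, 60, 0))
        pred = predict_single(part, rep, 100, 100, 60)
        assert (pred.status, pred.copyChange) == (PREDICTED, -10)

    def test_oracle_equivalence_sample(self, rng):
        mismatches = 0
        for _ in range(300):
            part, rs, re_, u = random_single_alignment_case(rng)
            rep = RepeatAnnotation("chr", rs, re_, "A" * u)
            f_left, f_right, n = far_near(u, (rs, part.refSrcSize - re_))
            got = predict_single(part, rep, f_left, f_right, n)
            want_status, want_change = predict_single_bruteforce(
                part, rs, re_, u, f_left, f_right, n)
            assert (got.status, got.copyChange) == (want_status, want_change)


class TestPredictMulti:
    def repeat(self):
        return RepeatAnnotation("chr1", 1005, 1015, "CAGGA")

    def test_insertion_between_flanking_parts(self):
        rep = self.repeat()
        parts = [part_at(500, 1000, 500, 1000), part_at(1020, 1520, 1520, 2020)]
        # both overlap? left ends at 1000 < 1005: give it overlap by extending
        parts = [part_at(500, 1006, 500, 1006), part_at(1014, 1520, 1514, 2020)]
        pred = predict_multi(parts, [0, 1], rep, 100, 100)
        # read gap 1514-1006=508, ref gap 1014-1006=8 -> insertion 500 -> +100
        assert (pred.status, pred.copyChange) == (PREDICTED, 100)

    def test_negative_insertion(self):
        rep = RepeatAnnotation("chr1", 1005, 1015, "CAG")
        parts = [part_at(500, 1006, 500, 1006), part_at(1044, 1550, 1014, 1520)]
        # read gap 8, ref gap 38 -> insertion -30 -> -10 copies
        pred = predict_multi(parts, [0, 1], rep, 100, 100)
        assert (pred.status, pred.copyChange) == (PREDICTED, -10)

    def test_middle_part_extending_past_left_edge_gives_up(self):
        rep = self.repeat()
        parts = [
            part_at(500, 1006, 500, 1006),
            part_at(700, 1010, 1100, 1410),  # extends >= f left of the repeat
            part_at(1014, 1520, 1514, 2020),
        ]
        pred = predict_multi(parts, [0, 1, 2], rep, 100, 100)
        assert pred.status == GAVE_UP

    def test_mixed_strands_give_up(self):
        rep = self.repeat()
        parts = [part_at(500, 1006, 500, 1006),
                 part_at(1014, 1520, 1514, 2020, strand="-")]
        assert predict_multi(parts, [0, 1], rep, 100, 100).status == GAVE_UP

    def test_non_consecutive_parts_give_up(self):
        rep = self.repeat()
        parts = [part_at(500, 1006, 500, 1006),
                 part_at(5000, 5100, 1100, 1200),
                 part_at(1014, 1520, 1514, 2020)]
        assert predict_multi(parts, [0, 2], rep, 100, 100).status == GAVE_UP

    def test_reverse_strand_left_is_last(self):
        rep = self.repeat()
        # '-' strand read: read order reversed relative to reference
        right = part_at(1014, 1520, 0, 506, strand="-")
        left = part_at(500, 1006, 1006, 1512, strand="-")
        parts = [right, left]  # read order
        pred = predict_multi(parts, [0, 1], rep, 100, 100)
        # read gap = left.readStart - right.readEnd = 1006-506 = 500
        # ref gap = 1014-1006 = 8 -> +492/5... use u=5: 492 -> 490 -> 98
        assert pred.status == PREDICTED
        assert pred.copyChange == round_to_unit(492, 5) // 5


class TestPredictRepeat:
    def test_end_to_end_both_strands(self, cag_locus, config):
        reads = []
        for k in range(10):
            strand = "+" if k < 5 else "-"
            reads.append(make_read(
                cag_locus, ReadSpec(name=f"r{k}", deltaCopies=49, strand=strand), seed=k))
        maf = "".join(edit_script_to_maf(r, mismap=1e-9) for r in reads)
        groups = read_maf(maf.splitlines(True))
        res = predict_repeat(groups, cag_locus.annotation, config)
        assert res.forwardChanges == [49] * 5
        assert res.reverseChanges == [49] * 5

    def test_read_far_from_repeat_is_no_coverage(self, config):
        from repeatlens.copy_number import predict_read
        part = part_at(5000, 5500, 0, 500)
        rep = RepeatAnnotation("chr1", 300, 360, "CAG")
        pred = predict_read([part], rep, config)
        assert pred.status == NO_COVERAGE

    def test_split_alignment_uses_multi_path(self, cag_locus, config):
        r = make_read(cag_locus, ReadSpec(name="s", deltaCopies=30, split=True), seed=5)
        groups = read_maf(edit_script_to_maf(r).splitlines(True))
        prepared = prepare_read(groups["s"], config)
        assert len(prepared) == 2  # not re-joinable: parts overlap on the reference
        res = predict_repeat(groups, cag_locus.annotation, config)
        assert res.forwardChanges == [30]


class TestSymmetries:
    def test_strand_symmetry(self, cag_locus, config):
        for delta in (-5, 0, 12, 40):
            preds = {}
            for strand in "+-":
                r = make_read(cag_locus,
                              ReadSpec(name="x", deltaCopies=delta, strand=strand), seed=3)
                groups = read_maf(edit_script_to_maf(r).splitlines(True))
                res = predict_repeat(groups, cag_locus.annotation, config)
                preds[strand] = (res.forwardChanges, res.reverseChanges)
            assert preds["+"] == ([delta], [])
            assert preds["-"] == ([], [delta])

    def test_mirror_symmetry(self, config):
        # reverse-complementing the whole locus preserves |copyChange|
        from repeatlens.annotations import reverse_complement
        from repeatlens.synthetic import LocusSpec, make_locus

        locus = build_locus("CAG", 15, seed=2)
        spec = locus.spec
        mirrored = make_locus(LocusSpec(
            leftFlank=reverse_complement(spec.rightFlank),
            rightFlank=reverse_complement(spec.leftFlank),
            unit=reverse_complement(spec.unit),
            refCopies=spec.refCopies,
            chrom="mir",
        ))
        for delta in (-4, 7, 33):
            changes = []
            for loc in (locus, mirrored):
                r = make_read(loc, ReadSpec(name="m", deltaCopies=delta), seed=9)
                groups = read_maf(edit_script_to_maf(r).splitlines(True))
                res = predict_repeat(groups, loc.annotation, config)
                changes.append(res.changes)
            assert abs(changes[0][0]) == abs(changes[1][0])
            assert changes[0][0] == delta
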