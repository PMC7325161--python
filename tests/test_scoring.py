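"""Evidence score formulas, retention partition, grading and ranking."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clipfuse.assembly import Contig
from clipfuse.genemodel import GeneModelSet
from clipfuse.scoring import (
    BreakpointScore,
    FusionCandidate,
    ScoreBreakdown,
    apply_retention_filters,
    assign_grade,
    combine_score,
    compute_area,
    grade_and_rank,
    score_breakpoint,
    weight_match,
    weight_taf,
)


class TestWeights:
    @pytest.mark.parametrize("taf,expected", [
        (0.01, 1.0), (0.5, 1.0), (0.005, math.exp(-2.0)),
    ])
    def test_taf_weight_piecewise(self, taf, expected):
        assert weight_taf(taf) == pytest.approx(expected, rel=1e-12)

    def test_taf_weight_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            weight_taf(0.0)

    @pytest.mark.parametrize("ml,rl,expected", [
        (50, 100, 1.0), (80, 100, 1.0), (46, 100, math.exp(-2.0)),
    ])
    def test_match_weight_piecewise(self, ml, rl, expected):
        assert weight_match(ml, rl) == pytest.approx(expected, rel=1e-12)

    def test_match_weight_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            weight_match(0, 100)

    @pytest.mark.parametrize("args,expected", [
        ((1, 1, 10, 0), 10.0), ((1, 1, 10, 1), 0.0), ((0.5, 1, 4, 0.5), 1.0),
    ])
    def test_breakpoint_score_product(self, args, expected):
        assert score_breakpoint(*args) == pytest.approx(expected)

    @pytest.mark.parametrize("args,expected", [
        ((1, 1, 1, 1), 1.0), ((0, 0, 2, 2), 0.0), ((3, 5, 2, 1), 8.0),
    ])
    def test_combined_score_formula(self, args, expected):
        assert combine_score(*args) == pytest.approx(expected)

    def test_frame_multiplier_doubles_score(self):
        assert combine_score(1, 1, 1, 2) / combine_score(1, 1, 1, 1) == 2.0

    def test_invalid_multipliers_rejected(self):
        with pytest.raises(ValueError):
            combine_score(1, 1, 3, 1)

    @given(st.floats(1e-6, 1.0), st.floats(1, 200), st.floats(0, 1e4),
           st.floats(0, 0.999))
    @settings(max_examples=200, deadline=None)
    def test_monotonicity_sweeps(self, taf, ml, area, repeat):
        """Score never decreases in TAF, match length or area; never increases in repeat."""
        s = score_breakpoint(weight_taf(taf), weight_match(ml, 200), area, repeat)
        s_taf = score_breakpoint(weight_taf(min(1.0, taf * 1.5)),
                                 weight_match(ml, 200), area, repeat)
        s_ml = score_breakpoint(weight_taf(taf), weight_match(ml + 10, 200),
                                area, repeat)
        s_area = score_breakpoint(weight_taf(taf), weight_match(ml, 200),
                                  area + 1, repeat)
        s_rep = score_breakpoint(weight_taf(taf), weight_match(ml, 200),
                                 area, min(0.999, repeat + 0.1))
        assert s_taf >= s - 1e-12 and s_ml >= s - 1e-12 and s_area >= s - 1e-12
        assert s_rep <= s + 1e-12

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_linearity_in_breakpoint_scores(self, p1, p2):
        assert combine_score(2 * p1, 2 * p2, 2, 2) == pytest.approx(
            2 * combine_score(p1, p2, 2, 2))


class TestArea:
    def test_sum_of_aligned_lengths(self):
        c = Contig(seq="A" * 200, depth=[],
                   members={"a/1": (0, 100), "b/1": (50, 150)})
        assert compute_area(c) == 200.0

    def test_partial_alignment_counts_aligned_bases(self):
        c = Contig(seq="A" * 100, depth=[], members={"a/1": (0, 75)})
        assert compute_area(c) == 75.0

    def test_no_reads_zero(self):
        assert compute_area(Contig(seq="A" * 10, depth=[], members={})) == 0.0

    def test_junction_restriction_keeps_crossing_reads_only(self):
        c = Contig(seq="A" * 300, depth=[],
                   members={"cross/1": (50, 150), "left/1": (0, 90),
                            "right/1": (120, 220)})
        assert compute_area(c, junction_q=100) == 100.0

    def test_union_mode_counts_covered_positions(self):
        c = Contig(seq="A" * 200, depth=[],
                   members={"a/1": (0, 100), "b/1": (50, 150)})
        assert compute_area(c, mode="union") == 150.0


def _breakdown(score_p=1.0, repeat=0.0, taf=0.02, ort=1, frame=1):
    bp = BreakpointScore(taf=taf, w_taf=1.0, match_length=100, w_match=1.0,
                         area=score_p, repeat=repeat, score=score_p * (1 - repeat))
    return ScoreBreakdown(bp1=bp, bp2=bp, ort=ort, frame=frame)


class _PairStub:
    def __init__(self, event_type="inter-chromosomal", readthrough=False):
        self.event_type = event_type
        self.readthrough_flag = readthrough
        self.bp1 = ("chr1", 100, "right")
        self.bp2 = ("chr2", 200, "left")


def _cand(gene_a="GA", gene_b="GB", score_p=10.0, repeat=0.0, taf=0.02,
          event_type="inter-chromosomal", readthrough=False, frame=1):
    from clipfuse.frame import FrameAnnotation
    c = FusionCandidate(pair=_PairStub(event_type, readthrough),
                        gene_a=gene_a, gene_b=gene_b,
                        frame=FrameAnnotation("unknown"))
    c.scores = _breakdown(score_p=score_p, repeat=repeat, taf=taf, frame=frame)
    return c


class TestRetention:
    EMPTY = GeneModelSet(transcripts=[])

    @pytest.mark.parametrize("kw,reason", [
        (dict(score_p=0.9), "score"),
        (dict(repeat=0.7, score_p=10), "repeat"),
        (dict(taf=0.005, score_p=10), "TAF"),
    ])
    def test_each_threshold_drops(self, kw, reason):
        kept, rejected = apply_retention_filters([_cand(**kw)], self.EMPTY)
        assert not kept and reason in rejected[0][1]

    def test_blacklisted_pair_removed_after_scoring(self):
        ms = GeneModelSet(transcripts=[], fusion_blacklist={frozenset(("GA", "GB"))})
        kept, rejected = apply_retention_filters([_cand()], ms)
        assert not kept and "blacklist" in rejected[0][1]

    def test_partition_matches_brute_force_on_randomized_breakdowns(self):
        import random
        rng = random.Random(13)
        cands = []
        for i in range(500):
            cands.append(_cand(gene_a=f"g{i}",
                               score_p=rng.uniform(0, 3),
                               repeat=rng.choice([0.0, 0.3, 0.69, 0.7, 0.9]),
                               taf=rng.choice([0.005, 0.01, 0.02, 0.2])))
        kept, rejected = apply_retention_filters(cands, self.EMPTY)
        expected = {
            id(c) for c in cands
            if c.scores.score >= 1.0
            and c.scores.bp1.repeat < 0.7 and c.scores.bp2.repeat < 0.7
            and c.scores.bp1.taf >= 0.01 and c.scores.bp2.taf >= 0.01
        }
        assert {id(c) for c in kept} == expected
        assert len(kept) + len(rejected) == 500


class TestGradingAndRanking:
    MODELS = GeneModelSet(transcripts=[],
                          known_fusions={frozenset(("KF1", "KF2"))},
                          itd_genes={"FLT3"})

    def test_known_fusion_and_itd_are_hq(self):
        assert assign_grade(_cand("KF1", "KF2"), self.MODELS) == "HQ"
        assert assign_grade(_cand("FLT3", "FLT3", event_type="ITD"), self.MODELS) == "HQ"

    def test_readthrough_and_novel_grades(self):
        assert assign_grade(_cand(readthrough=True), self.MODELS) == "RT"
        assert assign_grade(_cand(), self.MODELS) == "LQ"

    def test_hq_outranks_higher_scoring_lq_by_default(self):
        hq = _cand("KF1", "KF2", score_p=2)
        lq = _cand("GX", "GY", score_p=50)
        ranked = grade_and_rank([lq, hq], self.MODELS)
        assert [c.gene_a for c in ranked] == ["KF1", "GX"]
        assert [c.rank for c in ranked] == [1, 2]

    def test_raw_mode_ranks_by_score_alone(self):
        hq = _cand("KF1", "KF2", score_p=2)
        lq = _cand("GX", "GY", score_p=50)
        ranked = grade_and_rank([lq, hq], self.MODELS, raw_mode=True)
        assert [c.gene_a for c in ranked] == ["GX", "KF1"]

    def test_single_candidate_rank_one(self):
        (c,) = grade_and_rank([_cand()], self.MODELS)
        assert c.rank == 1

    def test_tier_order_hq_lq_rt(self):
        rt = _cand("GA", "GB", score_p=99, readthrough=True)
        lq = _cand("GC", "GD", score_p=1.5)
        hq = _cand("KF1", "KF2", score_p=1.2)
        ranked = grade_and_rank([rt, lq, hq], self.MODELS)
        assert [c.grade for c in ranked] == ["HQ", "LQ", "RT"]
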