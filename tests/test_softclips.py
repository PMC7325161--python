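"""Soft-clip extraction, clustering, expression weighting and filtering."""
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clipfuse.genemodel import GeneModelSet, LocusClass, TranscriptModel
from clipfuse.softclips import (
    FilterThresholds,
    SCRead,
    SoftClipCluster,
    cluster_softclips,
    compute_adjusted_expression,
    extract_softclips,
    filter_clusters,
)


def _segment(name, pos, cigar, seq, flag=0x1 | 0x40):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]})
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigarstring = cigar
    a.next_reference_id = 0
    a.next_reference_start = pos
    return a


class TestExtraction:
    def test_left_clip_position_and_sequence(self):
        rec = _segment("r", 1000, "30S70M", "A" * 30 + "C" * 70)
        (sc,) = extract_softclips([rec])
        assert (sc.clip_side, sc.clip_pos, sc.clip_len) == ("left", 1000, 30)
        assert sc.clipped_seq == "A" * 30

    def test_right_clip_at_end_of_aligned_block(self):
        rec = _segment("r", 1000, "70M30S", "C" * 70 + "A" * 30)
        (sc,) = extract_softclips([rec])
        assert (sc.clip_side, sc.clip_pos, sc.clip_len) == ("right", 1070, 30)

    def test_secondary_supplementary_duplicate_skipped(self):
        recs = [_segment("r", 1000, "30S70M", "A" * 100, flag=0x1 | f)
                for f in (0x100, 0x800, 0x400)]
        assert extract_softclips(recs) == []

    def test_unsorted_input_is_fatal(self):
        recs = [_segment("a", 2000, "10S90M", "A" * 100),
                _segment("b", 1000, "10S90M", "A" * 100)]
        with pytest.raises(ValueError, match="sort"):
            extract_softclips(recs)

    def test_planted_junction_reads_all_recovered(self, bam, fixture_set):
        screads = extract_softclips(bam.fetch())
        import pandas as pd
        truth = pd.read_csv(fixture_set["truth"], sep="\t")
        ab = truth[truth["name"] == "AB"].iloc[0]
        at_bp = [r for r in screads
                 if r.chrom == ab.chromA and r.clip_pos == ab.posA and r.clip_side == "right"]
        assert len(at_bp) == 4  # the planted clip-A support


def _scread(pos, side="right", clip_len=20, name=None):
    return SCRead(name=name or f"r{pos}.{clip_len}", chrom="chr1", clip_pos=pos,
                  clip_side=side, clip_len=clip_len, read_length=100,
                  clipped_seq="A" * clip_len, seq="A" * 100)


class TestClustering:
    def test_three_bp_chaining(self):
        cl = cluster_softclips([_scread(p) for p in (100, 102, 104)])
        assert len(cl) == 1 and cl[0].SC_cnt == 3

    def test_gap_over_three_bp_splits(self):
        cl = cluster_softclips([_scread(100), _scread(104)])
        assert len(cl) == 2

    def test_singleton_cluster(self):
        (cl,) = cluster_softclips([_scread(500)])
        assert cl.pos == 500 and cl.SC_cnt == 1

    def test_representative_is_longest_clip_then_leftmost(self):
        reads = [_scread(100, clip_len=10), _scread(102, clip_len=30),
                 _scread(103, clip_len=30)]
        (cl,) = cluster_softclips(reads)
        assert cl.pos == 102

    def test_sides_cluster_separately(self):
        cl = cluster_softclips([_scread(100, "left"), _scread(100, "right")])
        assert len(cl) == 2

    @given(st.lists(st.integers(0, 300), min_size=1, max_size=40), st.randoms())
    @settings(max_examples=50, deadline=None)
    def test_order_invariance_and_idempotence(self, positions, rnd):
        reads = [_scread(p, name=f"n{i}") for i, p in enumerate(positions)]
        base = cluster_softclips(reads)
        shuffled = list(reads)
        rnd.shuffle(shuffled)
        assert [(c.pos, c.SC_cnt) for c in cluster_softclips(shuffled)] == \
               [(c.pos, c.SC_cnt) for c in base]
        # positions of cluster representatives are stable under re-clustering
        reps = [r for c in base for r in c.members]
        assert [(c.pos, c.SC_cnt) for c in cluster_softclips(reps)] == \
               [(c.pos, c.SC_cnt) for c in base]


class TestAdjustedExpression:
    MODEL = TranscriptModel("T", "G", "c", "+", ((0, 2000),), 0, 0)

    def test_printed_formula(self):
        rec = compute_adjusted_expression("G", 100, 100, self.MODEL)
        assert rec.w == pytest.approx(0.8)
        assert rec.adjusted_gene_exp == pytest.approx(0.04)

    def test_twenty_bp_reads_are_weighted_to_zero(self):
        rec = compute_adjusted_expression("G", 100, 20, self.MODEL)
        assert rec.w == 0.0 and rec.adjusted_gene_exp == 0.0

    def test_zero_reads_zero_expression(self):
        assert compute_adjusted_expression("G", 0, 120, self.MODEL).adjusted_gene_exp == 0.0

    def test_empty_transcript_is_an_error(self):
        t = TranscriptModel("T", "G", "c", "+", ((0, 1),), 0, 0)
        t.exons = ()  # degenerate
        object.__setattr__(t, "exons", ())
        with pytest.raises(ValueError, match="empty transcript"):
            compute_adjusted_expression("G", 1, 100, t)


def _cluster(n, genic=True, taf=0.2, exp=0.05, pos=100, chrom="chr1"):
    c = SoftClipCluster(chrom=chrom, pos=pos, clip_side="right",
                        members=[_scread(pos, name=f"m{i}") for i in range(n)])
    c.locus = LocusClass(genic, ("G",) if genic else ())
    c.sc_taf = taf
    c.total_depth = max(1, int(n / taf))
    c.adjusted_gene_exp = exp if genic else None
    return c


class TestFiltering:
    EMPTY = GeneModelSet(transcripts=[])

    def test_passing_genic_cluster_retained(self):
        kept, rej = filter_clusters([_cluster(2, taf=0.1, exp=0.04)], self.EMPTY)
        assert len(kept) == 1 and not rej

    def test_intergenic_needs_five_clips(self):
        kept, rej = filter_clusters([_cluster(4, genic=False)], self.EMPTY)
        assert not kept and rej[0][1].startswith("SC_cnt")
        kept, _ = filter_clusters([_cluster(5, genic=False)], self.EMPTY)
        assert len(kept) == 1

    def test_taf_threshold_is_strict(self):
        kept, rej = filter_clusters([_cluster(3, taf=0.05)], self.EMPTY)
        assert not kept and "TAF" in rej[0][1]

    def test_low_expression_rejected(self):
        kept, rej = filter_clusters([_cluster(3, exp=0.009)], self.EMPTY)
        assert not kept and "exp" in rej[0][1]

    def test_blacklisted_site_rejected(self):
        ms = GeneModelSet(transcripts=[], blacklist_regions=[("chr1", 0, 1000)])
        kept, rej = filter_clusters([_cluster(5)], ms)
        assert not kept and rej[0][1] == "blacklist region"

    def test_output_subset_and_fixpoint(self):
        clusters = [_cluster(n, taf=t, exp=e)
                    for n in (1, 2, 5) for t in (0.01, 0.2) for e in (0.001, 0.05)]
        kept, rejected = filter_clusters(clusters, self.EMPTY)
        assert set(id(c) for c in kept) <= set(id(c) for c in clusters)
        assert len(kept) + len(rejected) == len(clusters)
        again, rej2 = filter_clusters(kept, self.EMPTY)
        assert again == kept and not rej2
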