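"""Seed-and-extend aligner, repeat score, partner resolution, event classes."""
import random

import pytest
from Bio import Align

from clipfuse.genemodel import revcomp
from clipfuse.genomealign import (
    AlignmentHit,
    GenomeIndex,
    ResolveConfig,
    align_contig,
    classify_event,
    compute_repeat_score,
    resolve_partner,
    segment_hit_pool,
)
from clipfuse.simulate import DUP_DST, DUP_SRC


@pytest.fixture(scope="module")
def index(genome):
    return GenomeIndex(genome)


def _sw_oracle():
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


class TestAligner:
    def test_exact_substring_single_perfect_hit(self, genome, index):
        q = genome["chr1"][7000:7060]
        hits = align_contig(q, index)
        best = hits[0]
        assert best.chrom == "chr1" and best.rstart == 7000 and best.rend == 7060
        assert best.matches == 60 and best.identity == 1.0

    def test_duplicated_segment_yields_two_equal_hits(self, genome, index):
        q = genome[DUP_SRC[0]][DUP_SRC[1]:DUP_SRC[1] + 80]
        hits = align_contig(q, index)
        assert len(hits) == 2
        assert hits[0].matches == hits[1].matches == 80
        assert {(h.chrom, h.rstart) for h in hits} == {
            (DUP_SRC[0], DUP_SRC[1]), (DUP_DST[0], DUP_DST[1])}

    def test_absent_query_gives_no_hits(self, genome, index):
        # verified absent by brute-force scan on both strands
        rng = random.Random(0)
        while True:
            q = "".join(rng.choice("ACGT") for _ in range(30))
            if all(q not in s and revcomp(q) not in s for s in genome.values()):
                break
        assert align_contig(q, index) == []

    def test_reverse_strand_query_found(self, genome, index):
        q = revcomp(genome["chr2"][3000:3070])
        best = align_contig(q, index)[0]
        assert best.strand == "-" and best.rstart == 3000 and best.rend == 3070

    def test_query_shorter_than_seed_is_empty(self, index):
        assert align_contig("ACGTACGT", index) == []

    def test_agrees_with_smith_waterman_oracle(self, genome, index):
        """Best locus and match count equal an independent local-DP oracle."""
        rng = random.Random(7)
        oracle = _sw_oracle()
        for _ in range(25):
            chrom = rng.choice(["chr1", "chr2"])
            n = rng.randrange(40, 200)
            start = rng.randrange(len(genome[chrom]) - n)
            q = list(genome[chrom][start:start + n])
            for k in range(len(q)):  # ~2% substitutions
                if rng.random() < 0.02:
                    q[k] = rng.choice([b for b in "ACGT" if b != q[k]])
            q = "".join(q)
            hits = align_contig(q, index, min_score=20)
            assert hits, f"no hit for query from {chrom}:{start}"
            best_scores = {}
            for c, s in genome.items():
                aln = oracle.align(s, q)
                best_scores[c] = aln.score if len(s) else 0
            oracle_chrom = max(sorted(best_scores), key=lambda c: best_scores[c])
            assert hits[0].score == max(best_scores.values())
            assert hits[0].chrom == oracle_chrom


class TestRepeatScore:
    def _hit(self, matches, rstart=0):
        return AlignmentHit(0, matches, "chr1", rstart, rstart + matches, "+",
                            matches, 0, 0, matches, 1.0)

    def test_unique_mapping_is_zero(self):
        h = self._hit(60)
        assert compute_repeat_score(h, [h]) == 0.0

    def test_two_equal_hits_half(self):
        a, b = self._hit(100), self._hit(100, 5000)
        assert compute_repeat_score(a, [a, b]) == pytest.approx(0.5)

    def test_unequal_hits(self):
        a, b = self._hit(90), self._hit(10, 5000)
        assert compute_repeat_score(a, [a, b]) == pytest.approx(0.1)

    def test_low_identity_hits_excluded_from_pool(self):
        a = self._hit(90)
        b = AlignmentHit(0, 100, "chr1", 5000, 5100, "+", 50, 50, 0, 0, 0.5)
        assert compute_repeat_score(a, [a, b]) == 0.0

    def test_empty_pool_raises(self):
        b = AlignmentHit(0, 100, "chr1", 0, 100, "+", 50, 50, 0, 0, 0.5)
        with pytest.raises(ValueError):
            compute_repeat_score(b, [b])

    def test_match_mass_normalization(self):
        hits = [self._hit(m, i * 1000) for i, m in enumerate((120, 60, 20))]
        total = sum(1 - compute_repeat_score(h, hits) for h in hits)
        assert total == pytest.approx(1.0)

    def test_segment_pool_excludes_partner_segment(self):
        bp1_hit = AlignmentHit(0, 100, "chr1", 0, 100, "+", 100, 0, 0, 100, 1.0)
        bp2_hit = AlignmentHit(100, 200, "chr2", 0, 100, "+", 100, 0, 0, 100, 1.0)
        assert segment_hit_pool(bp1_hit, [bp1_hit, bp2_hit]) == [bp1_hit]


class TestResolveAndClassify:
    def test_fixture_fusion_resolves_to_planted_partner(self, pipeline_result, fixture_set):
        import pandas as pd
        truth = pd.read_csv(fixture_set["truth"], sep="\t")
        ab = truth[truth["name"] == "AB"].iloc[0]
        row = pipeline_result.table
        m = row[(row.posA == ab.posA) & (row.posB == ab.posB)]
        assert len(m) == 1 and m.iloc[0].event_type == "inter-chromosomal"

    def test_full_length_paralogous_contig_rejected(self, genome, index, models):
        from clipfuse.softclips import SoftClipCluster
        # contig lies entirely inside the duplicated block: its full length
        # also maps to the copy on the other contig
        contig_seq = genome[DUP_SRC[0]][DUP_SRC[1] + 10:DUP_SRC[1] + 390]
        from clipfuse.assembly import Contig
        contig = Contig(seq=contig_seq, members={"x/1": (0, len(contig_seq))},
                        depth=[1] * len(contig_seq))
        bp = SoftClipCluster(chrom=DUP_SRC[0], pos=DUP_SRC[1] + 200,
                             clip_side="right", members=[])
        res = resolve_partner(bp, contig, models, index)
        from clipfuse.genomealign import Rejection
        assert isinstance(res, Rejection) and res.reason == "paralog artifact"

    def test_proximal_locus_preferred_for_multi_mapped_s2(self, genome, models):
        # build a genome where s2 maps equally to a nearby and a distant locus
        rng = random.Random(9)
        block = "".join(rng.choice("ACGT") for _ in range(80))
        g = {"c1": "".join(rng.choice("ACGT") for _ in range(50000)),
             "c2": "".join(rng.choice("ACGT") for _ in range(500)) + block
                   + "".join(rng.choice("ACGT") for _ in range(200))}
        # plant the same block ~40 kb from the discovery breakpoint on c1
        g1 = list(g["c1"])
        g1[40300:40380] = list(block)
        g["c1"] = "".join(g1)
        idx = GenomeIndex(g)
        from clipfuse.assembly import Contig
        from clipfuse.softclips import SoftClipCluster
        contig_seq = g["c1"][100:300] + block
        contig = Contig(seq=contig_seq, members={"x/1": (0, len(contig_seq))},
                        depth=[1] * len(contig_seq))
        bp = SoftClipCluster(chrom="c1", pos=300, clip_side="right", members=[])
        from clipfuse.genemodel import GeneModelSet
        res = resolve_partner(bp, contig, GeneModelSet(transcripts=[]), idx)
        assert not isinstance(res, type(None))
        assert res.bp2[0] == "c1" and abs(res.bp2[1] - 40300) <= 1

    def test_event_classification_on_recovered_candidates(self, pipeline_result):
        by_genes = {(r.geneA, r.geneB): r.event_type
                    for r in pipeline_result.table.itertuples()}
        assert by_genes[("FLT3", "FLT3")] == "ITD"
        assert by_genes[("GENE_A", "GENE_B")] == "inter-chromosomal"
        assert by_genes[("GENE_D1", "GENE_D2")] == "deletion-like"

    def test_orientation_multiplier(self, pipeline_result):
        for r in pipeline_result.candidates:
            if r.gene_b == "intergenic":
                assert r.pair.ort == 1
            else:
                assert r.pair.ort == 2
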