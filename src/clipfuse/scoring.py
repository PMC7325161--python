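"""Evidence-based scoring, retention filtering, grading and ranking.

Each breakpoint contributes

    score_p = w_TAF * w_Match * area * (1 - repeat(p))

where w_TAF is 1 for a transcript allelic fraction of at least 0.01 and
exp(-0.01/TAF) below it; w_Match is 1 when the matched contig length
reaches half the read length and exp((match_length - 0.5*read_length)/2)
below it; area is the summed length of junction-read subsequences mapped to
the fusion contig; and repeat is one minus the hit's share of matched bases
over all high-identity alignments.  The combined fusion score is

    score = 0.5 * (score_p(bp1) + score_p(bp2)) * ort * frame

with ort = 2 for orientation-consistent gene pairs and frame = 2 for
in-frame fusions (1 otherwise).  Candidates with score >= 1, both repeat
scores < 0.7 and both TAFs >= 0.01 are retained, graded HQ (known fusion or
ITD-gene match), RT (read-through) or LQ, and ranked HQ, LQ, RT with score
ordering inside each tier.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

from .assembly import Contig
from .frame import FrameAnnotation
from .genemodel import GeneModelSet
from .genomealign import BreakpointPair


def weight_taf(taf: float) -> float:
    if taf <= 0:
        raise ValueError("TAF must be positive")
    return 1.0 if taf >= 0.01 else math.exp(-0.01 / taf)


def weight_match(match_length: float, read_length: float) -> float:
    if match_length <= 0 or read_length <= 0:
        raise ValueError("match_length and read_length must be positive")
    half = 0.5 * read_length
    return 1.0 if match_length >= half else math.exp((match_length - half) / 2.0)


def score_breakpoint(w_taf: float, w_match: float, area: float, repeat: float) -> float:
    return w_taf * w_match * area * (1.0 - repeat)


def combine_score(score_p1: float, score_p2: float, ort: int, frame: int) -> float:
    if ort not in (1, 2) or frame not in (1, 2):
        raise ValueError("ort and frame must be 1 or 2")
    return 0.5 * (score_p1 + score_p2) * ort * frame


def compute_area(contig: Contig, junction_q: Optional[int] = None, mode: str = "sum") -> float:
    """Coverage of junction reads on the contig.

    ``sum``: total aligned length over member reads; ``union``: number of
    contig positions covered.  When ``junction_q`` is given, only members
    whose placement crosses the junction (junction reads proper) count.
    """
    if junction_q is None:
        members = contig.members.values()
    else:
        members = [iv for iv in contig.members.values() if iv[0] < junction_q < iv[1]]
    if mode == "sum":
        return float(sum(b - a for a, b in members))
    if mode == "union":
        covered = set()
        for a, b in members:
            covered.update(range(a, b))
        return float(len(covered))
    raise ValueError(f"unknown area mode {mode!r}")


@dataclass
class BreakpointScore:
    taf: float
    w_taf: float
    match_length: float
    w_match: float
    area: float
    repeat: float
    score: float

    @classmethod
    def compute(cls, taf, match_length, read_length, area, repeat):
        wt = weight_taf(taf)
        wm = weight_match(match_length, read_length)
        return cls(taf, wt, match_length, wm, area, repeat,
                   score_breakpoint(wt, wm, area, repeat))


@dataclass
class ScoreBreakdown:
    bp1: BreakpointScore
    bp2: BreakpointScore
    ort: int
    frame: int
    score: float = field(init=False)

    def __post_init__(self):
        self.score = combine_score(self.bp1.score, self.bp2.score, self.ort, self.frame)


@dataclass
class FusionCandidate:
    pair: BreakpointPair
    gene_a: str            # symbol or 'intergenic'
    gene_b: str
    frame: FrameAnnotation
    scores: Optional[ScoreBreakdown] = None
    grade: str = ""
    rank: int = 0
    evidence_reads: tuple = ()
    source: str = "softclip"  # 'softclip' | 'splice'


def apply_retention_filters(
    candidates: Iterable[FusionCandidate],
    models: GeneModelSet,
    min_score: float = 1.0,
    max_repeat: float = 0.7,
    min_taf: float = 0.01,
) -> Tuple[List[FusionCandidate], List[Tuple[FusionCandidate, str]]]:
    """Retain candidates with score >= 1, repeat < 0.7 and TAF >= 0.01 at both ends.

    Gene pairs on the fusion blacklist are removed here as well, after
    scoring, so diagnostics keep their score breakdowns.
    """
    kept, rejected = [], []
    for c in candidates:
        s = c.scores
        if s is None:
            raise ValueError("candidates must be scored before retention filtering")
        if s.score < min_score:
            rejected.append((c, f"score {s.score:.4g} < {min_score}"))
        elif not (s.bp1.repeat < max_repeat and s.bp2.repeat < max_repeat):
            rejected.append((c, f"repeat {s.bp1.repeat:.3f}/{s.bp2.repeat:.3f} >= {max_repeat}"))
        elif not (s.bp1.taf >= min_taf and s.bp2.taf >= min_taf):
            rejected.append((c, f"TAF {s.bp1.taf:.4f}/{s.bp2.taf:.4f} < {min_taf}"))
        elif models.pair_blacklisted(c.gene_a, c.gene_b):
            rejected.append((c, "fusion pair blacklisted"))
        else:
            kept.append(c)
    return kept, rejected


def assign_grade(c: FusionCandidate, models: GeneModelSet) -> str:
    """HQ for known fusion pairs or ITD-gene events, RT for read-throughs, else LQ."""
    if models.is_known_fusion(c.gene_a, c.gene_b):
        return "HQ"
    if c.pair.event_type == "ITD" and any(
        g in models.itd_genes for g in (c.gene_a, c.gene_b)
    ):
        return "HQ"
    if c.pair.readthrough_flag:
        return "RT"
    return "LQ"


_TIER = {"HQ": 0, "LQ": 1, "RT": 2}


def grade_and_rank(
    candidates: Iterable[FusionCandidate],
    models: GeneModelSet,
    raw_mode: bool = False,
) -> List[FusionCandidate]:
    """Grade, then rank HQ > LQ > RT with score order inside each tier.

    ``raw_mode`` ranks by fusion score alone.  Ties break lexicographically
    on (gene_a, gene_b, position) for determinism; ranks are 1..n.
    """
    cands = list(candidates)
    for c in cands:
        c.grade = assign_grade(c, models)
    tiebreak = lambda c: (c.gene_a, c.gene_b, c.pair.bp1[0], c.pair.bp1[1])
    if raw_mode:
        cands.sort(key=lambda c: (-c.scores.score,) + tiebreak(c))
    else:
        cands.sort(key=lambda c: (_TIER[c.grade], -c.scores.score) + tiebreak(c))
    for i, c in enumerate(cands, 1):
        c.rank = i
    return cands


OUTPUT_COLUMNS = [
    "sample", "geneA", "chrA", "posA", "sideA", "geneB", "chrB", "posB", "sideB",
    "event_type", "frame_status", "readsA", "readsB", "TAF_A", "TAF_B",
    "repeat_A", "repeat_B", "area", "score", "grade", "rank", "contig",
]


def candidate_row(c: FusionCandidate, sample: str) -> dict:
    s = c.scores
    return {
        "sample": sample,
        "geneA": c.gene_a, "chrA": c.pair.bp1[0], "posA": c.pair.bp1[1], "sideA": c.pair.bp1[2],
        "geneB": c.gene_b, "chrB": c.pair.bp2[0], "posB": c.pair.bp2[1], "sideB": c.pair.bp2[2],
        "event_type": c.pair.event_type,
        "frame_status": c.frame.status,
        "readsA": len(c.evidence_reads), "readsB": len(c.evidence_reads),
        "TAF_A": round(s.bp1.taf, 6), "TAF_B": round(s.bp2.taf, 6),
        "repeat_A": round(s.bp1.repeat, 6), "repeat_B": round(s.bp2.repeat, 6),
        "area": s.bp1.area, "score": round(s.score, 6),
        "grade": c.grade, "rank": c.rank,
        "contig": c.pair.contig.seq,
    }
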