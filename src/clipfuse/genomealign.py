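"""Contig re-alignment: seed-and-extend local alignment against the reference.

Contigs are mapped back to the genome in two rounds.  Round one aligns the
full contig: a contig whose (near-)full length maps contiguously to a
single locus away from the discovery breakpoint is discarded as a
paralogous-mapping artifact.  Otherwise the contig portion not explained by
the discovery-side hit (s2) is aligned in round two to locate the partner
breakpoint, preferring same-gene hits, then hits within 100 kb, then
alignment score.  The aligner is an 11-mer seed index over the reference
with full local dynamic programming inside each seeded window (match +1,
mismatch -1, gap -2); the hit score is matches minus penalties, mirroring a
BLAT-style minimum score of 25.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .assembly import Contig
from .genemodel import GeneModelSet, classify_locus, fetch_seq, revcomp
from .softclips import SoftClipCluster

logger = logging.getLogger("clipfuse")

MATCH, MISMATCH, GAP = 1, -1, -2
_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def _encode(s: str) -> np.ndarray:
    return _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]


@njit(cache=False)
def _sw_fill(q, w):
    """Smith-Waterman matrix fill; returns (H, best_i, best_j, best)."""
    lq, lw = q.shape[0], w.shape[0]
    H = np.zeros((lq + 1, lw + 1), dtype=np.int32)
    bi = bj = 0
    best = 0
    for i in range(1, lq + 1):
        qi = q[i - 1]
        for j in range(1, lw + 1):
            s = MATCH if (qi == w[j - 1] and qi < 4) else MISMATCH
            v = H[i - 1, j - 1] + s
            if H[i - 1, j] + GAP > v:
                v = H[i - 1, j] + GAP
            if H[i, j - 1] + GAP > v:
                v = H[i, j - 1] + GAP
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best = v
                bi, bj = i, j
    return H, bi, bj, best


def _traceback(H, q, w, bi, bj):
    """Walk back from the best cell.

    Returns (qstart, rstart, matches, mismatches, gaps, columns) where
    columns lists (q_idx, r_idx, is_match) for substitution columns in
    ascending reference order (gap columns are omitted).
    """
    i, j = bi, bj
    matches = mismatches = gaps = 0
    cols = []
    while i > 0 and j > 0 and H[i, j] > 0:
        s = MATCH if (q[i - 1] == w[j - 1] and q[i - 1] < 4) else MISMATCH
        if H[i, j] == H[i - 1, j - 1] + s:
            cols.append((i - 1, j - 1, s == MATCH))
            if s == MATCH:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
    cols.reverse()
    return i, j, matches, mismatches, gaps, cols


@dataclass
class AlignmentHit:
    qstart: int
    qend: int
    chrom: str
    rstart: int
    rend: int
    strand: str
    matches: int
    mismatches: int
    gaps: int
    score: int
    identity: float
    columns: Optional[list] = None  # (q, r, is_match) per substitution column

    def overlaps_point(self, chrom: str, pos: int, slack: int = 5) -> bool:
        return self.chrom == chrom and self.rstart - slack <= pos <= self.rend + slack


class GenomeIndex:
    """k-mer index of a small reference for seed-and-extend alignment."""

    def __init__(self, reference, k: int = 11):
        self.k = k
        self.seqs: Dict[str, str] = {}
        names = reference.keys() if hasattr(reference, "keys") else []
        for chrom in names:
            s = fetch_seq(reference, chrom, 0, len(reference[chrom]))
            self.seqs[chrom] = s
        self.codes = {c: _encode(s) for c, s in self.seqs.items()}
        self.index: Dict[str, list] = {}
        for chrom in sorted(self.seqs):
            s = self.seqs[chrom]
            for i in range(len(s) - k + 1):
                self.index.setdefault(s[i : i + k], []).append((chrom, i))


def _seed_groups(query: str, index: GenomeIndex, band: int = 24):
    """Cluster seed matches by (chrom, diagonal); yields candidate windows."""
    k = index.k
    seeds: Dict[str, list] = {}
    for i in range(len(query) - k + 1):
        for chrom, g in index.index.get(query[i : i + k], ()):
            seeds.setdefault(chrom, []).append((g - i, g))
    for chrom in sorted(seeds):
        lst = sorted(seeds[chrom])
        group: list = []
        prev_diag = None
        for diag, g in lst:
            if prev_diag is not None and diag - prev_diag > band:
                yield chrom, group
                group = []
            group.append((diag, g))
            prev_diag = diag
        if group:
            yield chrom, group


def align_contig(
    query: str,
    index: GenomeIndex,
    min_score: int = 25,
    max_hits: int = 3,
    pad: int = 32,
) -> List[AlignmentHit]:
    """Local alignments of ``query`` against the indexed reference.

    Both strands are searched; hits are local-DP optima within each seeded
    window, reported with score >= ``min_score``, sorted by descending score
    then genomic coordinate, truncated to ``max_hits``.  Query coordinates
    are always on the original (input) orientation.
    """
    lq = len(query)
    if lq < index.k:
        return []
    hits: List[AlignmentHit] = []
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        qc = _encode(q)
        for chrom, group in _seed_groups(q, index):
            diags = [d for d, _ in group]
            gmin = min(g for _, g in group)
            gmax = max(g for _, g in group)
            wlo = max(0, min(diags) - pad)
            whi = min(len(index.seqs[chrom]), max(diags) + lq + pad)
            wlo = min(wlo, max(0, gmin - pad))
            whi = max(whi, min(len(index.seqs[chrom]), gmax + index.k + pad))
            if whi - wlo < index.k:
                continue
            wc = index.codes[chrom][wlo:whi]
            H, bi, bj, best = _sw_fill(qc, wc)
            if best < min_score:
                continue
            qs, js, matches, mismatches, gaps, cols = _traceback(H, qc, wc, bi, bj)
            qe = bi
            rstart, rend = wlo + js, wlo + bj
            cols = [(q, wlo + r, m) for q, r, m in cols]
            if strand == "-":
                qs, qe = lq - qe, lq - qs
            hits.append(AlignmentHit(
                qstart=qs, qend=qe, chrom=chrom, rstart=rstart, rend=rend,
                strand=strand, matches=matches, mismatches=mismatches, gaps=gaps,
                score=int(best),
                identity=matches / max(1, matches + mismatches + gaps),
                columns=cols,
            ))
    # drop duplicate discoveries of the same alignment (same query AND ref span)
    hits.sort(key=lambda h: (-h.score, h.chrom, h.rstart, h.qstart))
    uniq: List[AlignmentHit] = []
    for h in hits:
        dup = False
        for u in uniq:
            if u.chrom == h.chrom and u.strand == h.strand:
                q_ov = min(u.qend, h.qend) - max(u.qstart, h.qstart)
                r_ov = min(u.rend, h.rend) - max(u.rstart, h.rstart)
                if q_ov > 0.5 * (h.qend - h.qstart) and r_ov > 0.5 * (h.rend - h.rstart):
                    dup = True
                    break
        if not dup:
            uniq.append(h)
    return uniq[:max_hits]


def compute_repeat_score(hit: AlignmentHit, all_hits: Sequence[AlignmentHit]) -> float:
    """repeat = 1 - matches(hit) / sum(matches) over hits with identity > 0.90.

    Zero means unique mapping; values approach 1 for highly repetitive
    contigs.
    """
    pool = [h for h in all_hits if h.identity > 0.90]
    if not pool:
        raise ValueError("repeat score undefined: no hits above identity threshold")
    if hit not in pool:
        raise ValueError("hit not among the high-identity hit set")
    return 1.0 - hit.matches / sum(h.matches for h in pool)


# ---------------------------------------------------------------------------
# Partner resolution and event classification
# ---------------------------------------------------------------------------

@dataclass
class BreakpointPair:
    bp1: tuple  # (chrom, pos, side)
    bp2: tuple
    s2: str
    contig: Contig
    junction_q: int            # contig coordinate of the junction
    hit_bp1: AlignmentHit
    hit_bp2: AlignmentHit
    hits_full: List[AlignmentHit]
    hits_s2: List[AlignmentHit]
    bp1_owns_prefix: bool = True  # contig[:junction_q] belongs to bp1
    event_type: str = ""
    readthrough_flag: bool = False
    ort: int = 1
    genes_a: tuple = ()
    genes_b: tuple = ()


@dataclass
class Rejection:
    reason: str
    chrom: str
    pos: int
    details: str = ""


@dataclass
class ResolveConfig:
    min_score: int = 25
    max_hits: int = 3
    proximity: int = 100_000
    full_map_frac: float = 0.95
    min_s2: int = 15
    readthrough_max: int = 200_000


def resolve_partner(
    bp: SoftClipCluster,
    contig: Contig,
    models: GeneModelSet,
    index: GenomeIndex,
    cfg: ResolveConfig = ResolveConfig(),
):
    """Two-round mapping of a contig: validate bp1, locate bp2.

    Returns a :class:`BreakpointPair` or a :class:`Rejection`.
    """
    seq = contig.seq
    hits = align_contig(seq, index, min_score=cfg.min_score, max_hits=cfg.max_hits)
    # the genuine bp1 hit terminates at the clip boundary: reads clip AT pos,
    # so a right-side clip aligns [x, pos) and a left-side clip [pos, y)
    slack = 5
    def _terminates_at_bp(h):
        if h.chrom != bp.chrom:
            return False
        edge = h.rend if bp.clip_side == "right" else h.rstart
        return abs(edge - bp.pos) <= slack
    anchored = [h for h in hits if _terminates_at_bp(h)]
    if not anchored:  # tolerate microhomology overshoot past the clip boundary
        anchored = [h for h in hits if h.overlaps_point(bp.chrom, bp.pos)]
    if not anchored:
        return Rejection("bp1 unconfirmed", bp.chrom, bp.pos,
                         f"{len(hits)} hits, none at the discovery breakpoint")
    for h in hits:
        if h not in anchored and (h.qend - h.qstart) >= cfg.full_map_frac * len(seq):
            return Rejection("paralog artifact", bp.chrom, bp.pos,
                             f"full contig maps to {h.chrom}:{h.rstart}")
    # prefer the anchored hit lying on the retained (non-clipped) side
    anchored.sort(key=lambda h: (-h.matches, h.qstart if bp.clip_side == "right" else -h.qend))
    h1 = anchored[0]
    jq, eff_side = _junction_on_contig(bp, contig, h1, len(seq))
    s2 = seq[jq:] if eff_side == "right" else seq[:jq]
    if len(s2) < cfg.min_s2:
        return Rejection("no partner sequence", bp.chrom, bp.pos,
                         f"s2 length {len(s2)} < {cfg.min_s2}")
    s2_hits = align_contig(s2, index, min_score=cfg.min_score, max_hits=cfg.max_hits)
    if not s2_hits:
        return Rejection("unmapped partner", bp.chrom, bp.pos,
                         f"no s2 hit with score >= {cfg.min_score}")

    genes1 = set(models.genes_at(bp.chrom, bp.pos))

    def priority(h: AlignmentHit):
        mid = (h.rstart + h.rend) // 2
        same_gene = bool(genes1 & set(models.genes_at(h.chrom, mid)))
        near = h.chrom == bp.chrom and abs(mid - bp.pos) <= cfg.proximity
        tier = 0 if same_gene else (1 if near else 2)
        return (tier, -h.score, h.chrom, h.rstart)

    h2 = min(s2_hits, key=priority)
    chrom2, pos2, side2 = _partner_breakpoint(h2, s2, eff_side)

    if models.in_blacklist(bp.chrom, bp.pos) and models.in_blacklist(chrom2, pos2):
        return Rejection("paralogous/V(D)J region", bp.chrom, bp.pos,
                         f"both breakpoints blacklisted (bp2 {chrom2}:{pos2})")

    return BreakpointPair(
        bp1=(bp.chrom, bp.pos, bp.clip_side),
        bp2=(chrom2, pos2, side2),
        s2=s2, contig=contig, junction_q=jq,
        hit_bp1=h1, hit_bp2=h2, hits_full=hits, hits_s2=s2_hits,
        bp1_owns_prefix=(eff_side == "right"),
    )


def _junction_on_contig(bp: SoftClipCluster, contig: Contig, h1: AlignmentHit,
                        contig_len: int):
    """Contig coordinate of the junction and the side of the partner segment.

    The representative clipped read's placement in the assembly pins the
    junction exactly (its aligned portion ends at the clip); when the
    cluster carries no members (splice-rescue pseudo-clusters) the junction
    is projected through the bp1 hit's alignment columns instead.  The
    returned side is 'right' when the partner sequence is the contig suffix.
    """
    if bp.members:
        rep = max(bp.members, key=lambda r: (r.clip_len, -r.clip_pos))
        uid = f"{rep.name}/{1 if rep.is_read1 else 2}"
        iv = contig.members.get(uid)
        if iv is not None:
            rc = contig.orientations.get(uid, False)
            if (bp.clip_side == "right") == (not rc):
                jq = iv[1] - rep.clip_len
                eff = "right"
            else:
                jq = iv[0] + rep.clip_len
                eff = "left"
            return max(0, min(contig_len, jq)), eff
    # fall back to the alignment mapping of the clip position
    eff = bp.clip_side if h1.strand == "+" else ("left" if bp.clip_side == "right" else "right")
    target = bp.pos - 1 if bp.clip_side == "right" else bp.pos
    jq = None
    if h1.columns:
        for q, r, _m in h1.columns:
            if r == target:
                q_orig = q if h1.strand == "+" else contig_len - 1 - q
                jq = q_orig + 1 if eff == "right" else q_orig
                break
    if jq is None:
        if h1.strand == "+":
            jq = h1.qstart + (bp.pos - h1.rstart)
        else:
            jq = h1.qend - (bp.pos - h1.rstart)
    return max(0, min(contig_len, jq)), eff


def _partner_breakpoint(h: AlignmentHit, s2: str, clip_side: str):
    """Genomic coordinate and side of bp2 from the s2 alignment.

    For a right-side clip s2 is the contig suffix whose first base abuts the
    junction; for a left-side clip it is the prefix whose last base does.
    The breakpoint is the junction-facing boundary of the alignment itself:
    unaligned s2 termini are non-templated insertions and are not projected
    onto the reference.  Because local alignment can glue a net-positive
    but mismatch-riddled run of insertion bases onto the true hit, the
    junction-facing end is first trimmed back until its terminal columns
    are exact matches.
    """
    junction_low_r = (clip_side == "right") == (h.strand == "+")
    cols = h.columns or []
    if cols:
        cols = _trim_junction_noise(cols, junction_low_r)
    if junction_low_r:
        pos = cols[0][1] if cols else h.rstart
    else:
        pos = cols[-1][1] + 1 if cols else h.rend
    if clip_side == "right":
        side = "left" if h.strand == "+" else "right"
    else:
        side = "right" if h.strand == "+" else "left"
    return h.chrom, pos, side


def _trim_junction_noise(cols, junction_low_r: bool, window: int = 5):
    """Drop junction-facing columns until the terminal ``window`` are all matches."""
    cols = list(cols)
    while len(cols) > window:
        edge = cols[:window] if junction_low_r else cols[-window:]
        if all(m for _, _, m in edge):
            break
        if junction_low_r:
            cols.pop(0)
        else:
            cols.pop()
    return cols


def segment_hit_pool(hit: AlignmentHit, all_hits: Sequence[AlignmentHit],
                     min_frac: float = 0.5) -> List[AlignmentHit]:
    """Hits competing for the same contig segment as ``hit``.

    The repeat score of a breakpoint compares a hit only against alternative
    mappings of its own segment, not against the partner segment's hit;
    alternatives are hits whose query interval overlaps the hit's by at
    least ``min_frac`` of the shorter interval.
    """
    pool = []
    for h in all_hits:
        ov = min(h.qend, hit.qend) - max(h.qstart, hit.qstart)
        shorter = min(h.qend - h.qstart, hit.qend - hit.qstart)
        if ov >= min_frac * max(1, shorter):
            pool.append(h)
    return pool


def classify_event(pair: BreakpointPair, models: GeneModelSet,
                   cfg: ResolveConfig = ResolveConfig()) -> BreakpointPair:
    """Assign event type, read-through flag and the orientation multiplier.

    ``ort`` is 2 when the contig geometry is consistent with both partner
    genes' transcription orientations (either contig reading direction),
    otherwise 1.  An in-gene pair with tandem-duplication geometry is an
    ITD; same-strand adjacent gene pairs with deletion geometry are flagged
    read-through.
    """
    c1, p1, side1 = pair.bp1
    c2, p2, side2 = pair.bp2
    pair.genes_a = models.genes_at(c1, p1)
    pair.genes_b = models.genes_at(c2, p2)
    shared = set(pair.genes_a) & set(pair.genes_b)

    dup_geom = (side1 == "right" and side2 == "left" and c1 == c2 and p2 < p1) or (
        side1 == "left" and side2 == "right" and c1 == c2 and p2 > p1
    )
    del_geom = (side1 == "right" and side2 == "left" and c1 == c2 and p2 > p1) or (
        side1 == "left" and side2 == "right" and c1 == c2 and p2 < p1
    )

    if c1 != c2:
        pair.event_type = "inter-chromosomal"
    elif shared and dup_geom and pair.hit_bp1.strand == pair.hit_bp2.strand:
        pair.event_type = "ITD"
    elif shared:
        pair.event_type = "internal"
    elif not pair.genes_a and not pair.genes_b:
        pair.event_type = "intergenic"
    elif pair.hit_bp1.strand != pair.hit_bp2.strand:
        pair.event_type = "inversion-like"
    elif del_geom:
        pair.event_type = "deletion-like"
    elif dup_geom:
        pair.event_type = "duplication-like"
    else:
        pair.event_type = "internal"

    # read-through: same-strand neighbors joined with deletion geometry
    pair.readthrough_flag = False
    if del_geom and pair.genes_a and pair.genes_b and not shared:
        upstream = pair.genes_a if side1 == "right" else pair.genes_b
        downstream = pair.genes_b if side1 == "right" else pair.genes_a
        for ga in upstream:
            nb = models.downstream_neighbor(ga)
            if nb and nb[0] in downstream and nb[1] <= cfg.readthrough_max:
                pair.readthrough_flag = True
                break

    # orientation multiplier
    pair.ort = 1
    if pair.genes_a and pair.genes_b:
        g1 = {models.longest_isoform(g).strand for g in pair.genes_a}
        g2 = {models.longest_isoform(g).strand for g in pair.genes_b}
        d1, d2 = pair.hit_bp1.strand, pair.hit_bp2.strand
        for s1 in g1:
            for s2_ in g2:
                if (d1 == s1) == (d2 == s2_):
                    pair.ort = 2
    return pair
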