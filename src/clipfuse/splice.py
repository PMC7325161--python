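"""Rescue of deletion-type fusions mapped as novel splice junctions.

RNA mappers may represent a deletion-driven fusion junction as a spliced
alignment (an N CIGAR operation) instead of a soft clip, so such events
leave no clip clusters.  This module harvests junctions from N operations,
drops any junction matching an annotated intron, and rescues those that
span at least 10 kb, encompass at least two genes, and have a junction-read
transcript allelic fraction above 0.01.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Tuple

from .genemodel import GeneModelSet

logger = logging.getLogger("clipfuse")

_FLAG_SKIP = 0x100 | 0x800 | 0x400


@dataclass
class NovelJunction:
    chrom: str
    donor_pos: int       # reference position of the last aligned base + 1 (junction start)
    acceptor_pos: int    # reference position where alignment resumes
    reads: List[Tuple[str, str]] = field(default_factory=list)  # (uid, seq)
    taf: Optional[float] = None
    genes_donor: tuple = ()
    genes_acceptor: tuple = ()

    @property
    def span(self) -> int:
        return self.acceptor_pos - self.donor_pos

    @property
    def junction_read_cnt(self) -> int:
        return len(self.reads)

    @property
    def genes_spanned(self) -> set:
        return set(self.genes_donor) | set(self.genes_acceptor)


def annotated_introns(models: GeneModelSet) -> set:
    out = set()
    for t in models.transcripts:
        for (a1, b1), (a2, b2) in zip(t.exons, t.exons[1:]):
            out.add((t.chrom, b1, a2))
    return out


def harvest_novel_junctions(alignments: Iterable, models: GeneModelSet) -> List[NovelJunction]:
    """Collect splice junctions from N CIGAR ops that are absent from the gene model.

    Junctions with identical donor/acceptor to an annotated intron are
    dropped; read support is aggregated per junction.
    """
    known = annotated_introns(models)
    agg: Dict[tuple, NovelJunction] = {}
    for rec in alignments:
        if rec.is_unmapped or (rec.flag & _FLAG_SKIP):
            continue
        cig = rec.cigartuples
        if not cig or not any(op == 3 for op, _ in cig):
            continue
        ref = rec.reference_start
        for op, ln in cig:
            if op == 3:  # N
                key = (rec.reference_name, ref, ref + ln)
                if key not in known:
                    j = agg.setdefault(key, NovelJunction(
                        chrom=rec.reference_name, donor_pos=ref, acceptor_pos=ref + ln))
                    uid = f"{rec.query_name}/{2 if rec.is_read2 else 1}"
                    if rec.query_sequence:
                        j.reads.append((uid, rec.query_sequence))
                ref += ln
            elif op in (0, 2, 7, 8):  # M, D, =, X consume reference
                ref += ln
    out = sorted(agg.values(), key=lambda j: (j.chrom, j.donor_pos, j.acceptor_pos))
    for j in out:
        j.genes_donor = models.genes_at(j.chrom, j.donor_pos)
        j.genes_acceptor = models.genes_at(j.chrom, j.acceptor_pos)
    return out


def annotate_junction_taf(junctions: Iterable[NovelJunction],
                          depth_fn: Callable[[str, int], int]) -> None:
    """TAF = junction reads / reads overlapping the donor position (local depth)."""
    for j in junctions:
        depth = max(depth_fn(j.chrom, j.donor_pos), j.junction_read_cnt)
        j.taf = j.junction_read_cnt / depth


def rescue_candidates(
    junctions: Iterable[NovelJunction],
    models: GeneModelSet,
    min_span: int = 10_000,
    min_taf: float = 0.01,
) -> List[NovelJunction]:
    """Junctions that qualify as fusion candidates.

    Requires span >= ``min_span``, at least two distinct genes across the
    two junction ends, and junction TAF strictly above ``min_taf``.
    """
    kept = []
    for j in junctions:
        if j.span < min_span:
            logger.debug("junction %s:%d-%d rejected: span %d", j.chrom, j.donor_pos,
                         j.acceptor_pos, j.span)
            continue
        if len(j.genes_spanned) < 2:
            logger.debug("junction %s:%d-%d rejected: single gene", j.chrom,
                         j.donor_pos, j.acceptor_pos)
            continue
        if j.taf is None or not j.taf > min_taf:
            logger.debug("junction %s:%d-%d rejected: TAF %s", j.chrom, j.donor_pos,
                         j.acceptor_pos, j.taf)
            continue
        kept.append(j)
    return kept
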