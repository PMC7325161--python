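"""Soft-clip extraction, clustering, and candidate-breakpoint filtering.

A read whose CIGAR carries a terminal S operation marks a potential fusion
junction: the clipped tail belongs to the partner locus.  Clips within 3 bp
of one another (same side) are chained into a cluster whose representative
position is the clip position of the member with the longest clipped
subsequence.  Clusters are then screened with four retention criteria:
minimum clip support (genic 2 / intergenic 5), minimum adjusted gene
expression (genic only), exclusion of blacklisted paralogous regions, and a
local transcriptional allelic fraction above 0.05.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Mapping, Optional, Tuple

from .genemodel import GeneModelSet, LocusClass, TranscriptModel, classify_locus

logger = logging.getLogger("clipfuse")

_FLAG_SKIP = 0x100 | 0x800 | 0x400  # secondary, supplementary, duplicate


@dataclass
class SCRead:
    name: str
    chrom: str
    clip_pos: int          # genomic coordinate of the clip boundary
    clip_side: str         # 'left' | 'right'
    clip_len: int
    read_length: int
    clipped_seq: str
    seq: str               # full read sequence (aligned orientation)
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    mate_mapped: bool = False
    is_read1: bool = True

    def __post_init__(self):
        if not (1 <= self.clip_len <= self.read_length):
            raise ValueError("clip_len out of range")


@dataclass
class SoftClipCluster:
    chrom: str
    pos: int               # clip_pos of the member with the longest clip
    clip_side: str
    members: List[SCRead]
    # annotated later:
    total_depth: Optional[int] = None
    sc_taf: Optional[float] = None
    locus: Optional[LocusClass] = None
    adjusted_gene_exp: Optional[float] = None

    @property
    def SC_cnt(self) -> int:
        return len(self.members)


@dataclass
class GeneExpressionRecord:
    gene: str
    read_cnt: int
    mRNA_length: int
    w: float
    adjusted_gene_exp: float


@dataclass
class FilterThresholds:
    min_sc_genic: int = 2
    min_sc_intergenic: int = 5
    min_exp: float = 0.01
    min_sc_taf: float = 0.05


def extract_softclips(alignments: Iterable, min_clip: int = 1) -> List[SCRead]:
    """One SCRead per soft-clipped read end with clip length >= ``min_clip``.

    ``alignments`` is a pysam AlignmentFile (or any iterable of
    AlignedSegment) in coordinate order; secondary, supplementary and
    duplicate-flagged records are skipped.  Out-of-order input is a fatal
    error.
    """
    out: List[SCRead] = []
    last = None
    for rec in alignments:
        if rec.is_unmapped or (rec.flag & _FLAG_SKIP):
            continue
        key = (rec.reference_id, rec.reference_start)
        if last is not None and key < last:
            raise ValueError(
                "input alignments are not coordinate-sorted; sort with 'samtools sort' first"
            )
        last = key
        cig = rec.cigartuples
        seq = rec.query_sequence
        if not cig or seq is None:
            continue
        common = dict(
            name=rec.query_name,
            chrom=rec.reference_name,
            read_length=len(seq),
            seq=seq,
            mate_chrom=rec.next_reference_name if not rec.mate_is_unmapped else None,
            mate_pos=rec.next_reference_start if not rec.mate_is_unmapped else None,
            mate_mapped=not rec.mate_is_unmapped if rec.is_paired else False,
            is_read1=not rec.is_read2,
        )
        # skip over hard clips at the termini
        first = cig[1] if cig[0][0] == 5 and len(cig) > 1 else cig[0]
        last_op = cig[-2] if cig[-1][0] == 5 and len(cig) > 1 else cig[-1]
        if first[0] == 4 and first[1] >= min_clip:
            out.append(SCRead(
                clip_pos=rec.reference_start, clip_side="left",
                clip_len=first[1], clipped_seq=seq[: first[1]], **common,
            ))
        if last_op[0] == 4 and last_op[1] >= min_clip and last_op is not first:
            out.append(SCRead(
                clip_pos=rec.reference_end, clip_side="right",
                clip_len=last_op[1], clipped_seq=seq[-last_op[1]:], **common,
            ))
    return out


def cluster_softclips(screads: Iterable[SCRead], window: int = 3) -> List[SoftClipCluster]:
    """Single-linkage chaining of same-side clips within ``window`` bp.

    The representative position is the clip position of the longest-clip
    member (ties: leftmost).  Left- and right-side clips cluster separately.
    """
    groups: dict = {}
    for r in screads:
        groups.setdefault((r.chrom, r.clip_side), []).append(r)
    clusters: List[SoftClipCluster] = []
    for (chrom, side), reads in sorted(groups.items()):
        reads.sort(key=lambda r: (r.clip_pos, -r.clip_len, r.name))
        chain: List[SCRead] = []
        for r in reads:
            if chain and r.clip_pos - chain[-1].clip_pos > window:
                clusters.append(_make_cluster(chrom, side, chain))
                chain = []
            chain.append(r)
        if chain:
            clusters.append(_make_cluster(chrom, side, chain))
    clusters.sort(key=lambda c: (c.chrom, c.pos, c.clip_side))
    return clusters


def _make_cluster(chrom: str, side: str, members: List[SCRead]) -> SoftClipCluster:
    rep = max(members, key=lambda r: (r.clip_len, -r.clip_pos))
    return SoftClipCluster(chrom=chrom, pos=rep.clip_pos, clip_side=side, members=list(members))


def compute_adjusted_expression(
    gene: str, read_cnt: int, read_length: int, model: TranscriptModel
) -> GeneExpressionRecord:
    """adjusted_gene_exp = w * read_cnt / mRNA_length, w = (read_length-20)/100 floored at 0."""
    if model.mRNA_length == 0:
        raise ValueError("empty transcript")
    w = max(0.0, (read_length - 20) / 100.0)
    return GeneExpressionRecord(
        gene=gene, read_cnt=read_cnt, mRNA_length=model.mRNA_length,
        w=w, adjusted_gene_exp=w * read_cnt / model.mRNA_length,
    )


def annotate_clusters(
    clusters: Iterable[SoftClipCluster],
    models: GeneModelSet,
    depth_fn: Callable[[str, int], int],
    expression: Mapping[str, GeneExpressionRecord],
) -> None:
    """Attach locus class, local depth, SC_TAF and expression to each cluster.

    The TAF denominator is the number of mapped reads overlapping the
    cluster position (local depth), never less than the clip count itself.
    For genic clusters the expression value is the maximum adjusted
    expression over all overlapping genes.
    """
    for c in clusters:
        c.locus = classify_locus(c.chrom, c.pos, models)
        depth = max(depth_fn(c.chrom, c.pos), c.SC_cnt)
        c.total_depth = depth
        c.sc_taf = c.SC_cnt / depth
        if c.locus.genic:
            vals = [expression[g].adjusted_gene_exp for g in c.locus.genes if g in expression]
            c.adjusted_gene_exp = max(vals) if vals else 0.0


def filter_clusters(
    clusters: Iterable[SoftClipCluster],
    models: GeneModelSet,
    thresholds: FilterThresholds = FilterThresholds(),
) -> Tuple[List[SoftClipCluster], List[Tuple[SoftClipCluster, str]]]:
    """Apply the four retention criteria; returns (retained, rejections).

    Clusters must already be annotated (see :func:`annotate_clusters`).
    """
    th = thresholds
    kept: List[SoftClipCluster] = []
    rejected: List[Tuple[SoftClipCluster, str]] = []

    def reject(c, reason):
        logger.debug("cluster %s:%d (%s) rejected: %s", c.chrom, c.pos, c.clip_side, reason)
        rejected.append((c, reason))

    for c in clusters:
        if c.locus is None or c.sc_taf is None:
            raise ValueError("clusters must be annotated before filtering")
        if models.in_blacklist(c.chrom, c.pos):
            reject(c, "blacklist region")
            continue
        if c.locus.genic:
            if c.SC_cnt < th.min_sc_genic:
                reject(c, f"SC_cnt {c.SC_cnt} < {th.min_sc_genic} (genic)")
                continue
            if (c.adjusted_gene_exp or 0.0) < th.min_exp:
                reject(c, f"adjusted_gene_exp {c.adjusted_gene_exp} < {th.min_exp}")
                continue
        else:
            if c.SC_cnt < th.min_sc_intergenic:
                reject(c, f"SC_cnt {c.SC_cnt} < {th.min_sc_intergenic} (intergenic)")
                continue
        if not c.sc_taf > th.min_sc_taf:
            reject(c, f"SC_TAF {c.sc_taf:.4f} <= {th.min_sc_taf}")
            continue
        kept.append(c)
    return kept, rejected
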