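"""End-to-end fusion calling: discover, assemble, map, rescue, annotate, rank.

Stages run in a fixed order: soft-clip clustering and filtering; per-cluster
read collection and assembly; two-round contig mapping; splice-junction
rescue; merging of the two candidate streams; reading-frame annotation;
scoring, retention filtering, grading and ranking.  Output is a TSV with a
fixed, versioned column order, a diagnostics TSV of rejections, a copy of
the effective configuration, and a log.  Runs are deterministic: the same
configuration and inputs produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import pyfaidx
import pysam
import yaml

from . import assembly as asm
from . import genomealign as ga
from . import scoring as sc
from . import softclips as scl
from . import splice as spl
from .frame import FrameAnnotation, annotate_frame
from .genemodel import GeneModelSet, load_gene_model
from .scoring import FusionCandidate

logger = logging.getLogger("clipfuse")


@dataclass
class RunConfig:
    """All inputs and thresholds; defaults are the published values."""

    bam: str = ""
    reference: str = ""
    refflat: str = ""
    proteins: Optional[str] = None
    known_fusions: Optional[str] = None
    itd_genes: Optional[str] = None
    blacklist: Optional[str] = None
    fusion_blacklist: Optional[str] = None
    out_dir: str = "clipfuse_out"
    sample: str = "sample"
    seed: int = 0
    raw_mode: bool = False
    # breakpoint discovery
    min_clip: int = 1
    cluster_window: int = 3
    min_sc_genic: int = 2
    min_sc_intergenic: int = 5
    min_exp: float = 0.01
    min_sc_taf: float = 0.05
    # assembly
    collect_window: int = 1000
    asm_min_overlap: int = 25
    asm_min_identity: float = 0.9
    # contig mapping
    min_align_score: int = 25
    max_hits: int = 3
    proximity_kb: int = 100
    # splice rescue
    rescue_min_span: int = 10_000
    rescue_min_taf: float = 0.01
    # retention
    min_fusion_score: float = 1.0
    max_repeat: float = 0.7
    min_retention_taf: float = 0.01
    area_mode: str = "sum"
    merge_window: int = 5

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    candidates: List[FusionCandidate]
    table: pd.DataFrame
    counts: Dict[str, int]
    output_path: Optional[Path] = None


def _depth_fn(bam):
    def depth(chrom, pos):
        try:
            return bam.count(chrom, pos, pos + 1,
                             read_callback=lambda r: not (r.flag & 0x704))
        except ValueError:
            return 0
    return depth


def gene_read_counts(bam, models: GeneModelSet) -> Dict[str, int]:
    """Primary-alignment read starts inside each gene's transcription span."""
    counts: Dict[str, int] = {}
    for rec in bam.fetch():
        if rec.is_unmapped or (rec.flag & 0x704):
            continue
        for g in models.genes_at(rec.reference_name, rec.reference_start):
            counts[g] = counts.get(g, 0) + 1
    if hasattr(bam, "reset"):
        bam.reset()
    return counts


def _modal_read_length(bam, n: int = 1000) -> int:
    lens: Dict[int, int] = {}
    for i, rec in enumerate(bam.fetch()):
        if rec.query_sequence:
            L = len(rec.query_sequence)
            lens[L] = lens.get(L, 0) + 1
        if i >= n:
            break
    if hasattr(bam, "reset"):
        bam.reset()
    if not lens:
        return 100
    return max(lens.items(), key=lambda kv: (kv[1], kv[0]))[0]


def _expression_records(bam, models, read_length):
    counts = gene_read_counts(bam, models)
    out = {}
    for g, ts in models.by_gene.items():
        t = models.longest_isoform(g)
        out[g] = scl.compute_adjusted_expression(g, counts.get(g, 0), read_length, t)
    return out


def _nearby_cluster(clusters, chrom, pos, side, window=3):
    for c in clusters:
        if c.chrom == chrom and c.clip_side == side and abs(c.pos - pos) <= window:
            return c
    return None


def _score_candidate(cand, bam_depth, all_clusters, read_length, area_mode):
    """Per-breakpoint TAF / match length / repeat, then the combined score."""
    pair = cand.pair
    contig = pair.contig
    area = sc.compute_area(contig, junction_q=pair.junction_q, mode=area_mode)
    n_junction = max(1, sum(1 for a, b in contig.members.values()
                            if a < pair.junction_q < b))

    def side_stats(bp, hit, all_hits, support):
        chrom, pos, _side = bp
        depth = max(bam_depth(chrom, pos), support)
        taf = support / depth
        pool = ga.segment_hit_pool(hit, all_hits)
        repeat = ga.compute_repeat_score(hit, pool) if any(
            h.identity > 0.9 for h in pool) else 0.0
        match_length = max(1, hit.matches)
        return taf, match_length, repeat

    sup1 = cand.support_bp1 or n_junction
    sup2 = cand.support_bp2 or n_junction
    taf1, ml1, rep1 = side_stats(pair.bp1, pair.hit_bp1, pair.hits_full, sup1)
    taf2, ml2, rep2 = side_stats(pair.bp2, pair.hit_bp2, pair.hits_s2, sup2)
    if cand.source == "splice":
        ml1 = ml2 = read_length  # junction reads are fully mapped
    bp1 = sc.BreakpointScore.compute(taf1, ml1, read_length, area, rep1)
    bp2 = sc.BreakpointScore.compute(taf2, ml2, read_length, area, rep2)
    cand.scores = sc.ScoreBreakdown(bp1=bp1, bp2=bp2, ort=pair.ort,
                                    frame=cand.frame.multiplier)


@dataclass
class _Candidate(FusionCandidate):
    support_bp1: int = 0
    support_bp2: int = 0


def _merge_candidates(cands: List[_Candidate], window: int) -> List[_Candidate]:
    """Collapse candidates sharing both breakpoints (unordered, within window bp)."""
    cands = sorted(
        cands,
        key=lambda c: (0 if c.source == "softclip" else 1,
                       0 if c.pair.bp1[2] == "right" else 1,
                       -len(c.evidence_reads),
                       c.pair.bp1[0], c.pair.bp1[1]),
    )
    kept: List[_Candidate] = []
    for c in cands:
        ends_c = sorted([(c.pair.bp1[0], c.pair.bp1[1]), (c.pair.bp2[0], c.pair.bp2[1])])
        merged = False
        for k in kept:
            ends_k = sorted([(k.pair.bp1[0], k.pair.bp1[1]), (k.pair.bp2[0], k.pair.bp2[1])])
            if all(a[0] == b[0] and abs(a[1] - b[1]) <= window
                   for a, b in zip(ends_c, ends_k)):
                k.evidence_reads = tuple(sorted(set(k.evidence_reads) | set(c.evidence_reads)))
                merged = True
                break
        if not merged:
            kept.append(c)
    return kept


def run_pipeline(config: RunConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    counts: Dict[str, int] = {}
    diagnostics: List[dict] = []
    try:
        reference = pyfaidx.Fasta(config.reference)
        models = load_gene_model(
            config.refflat, reference, proteins=config.proteins,
            known_fusions=config.known_fusions, itd_genes=config.itd_genes,
            blacklist_regions=config.blacklist,
            fusion_blacklist=config.fusion_blacklist,
        )
        index = ga.GenomeIndex(reference)
        rcfg = ga.ResolveConfig(
            min_score=config.min_align_score, max_hits=config.max_hits,
            proximity=config.proximity_kb * 1000,
        )
        bam = pysam.AlignmentFile(config.bam)
        depth = _depth_fn(bam)
        read_length = _modal_read_length(bam)
        insert_bound = asm.estimate_insert_bound(bam)
        expression = _expression_records(bam, models, read_length)

        # --- breakpoint discovery -------------------------------------------------
        screads = scl.extract_softclips(bam.fetch(), min_clip=config.min_clip)
        clusters = scl.cluster_softclips(screads, window=config.cluster_window)
        scl.annotate_clusters(clusters, models, depth, expression)
        kept, rejected = scl.filter_clusters(clusters, models, scl.FilterThresholds(
            config.min_sc_genic, config.min_sc_intergenic,
            config.min_exp, config.min_sc_taf,
        ))
        counts["sc_reads"] = len(screads)
        counts["clusters"] = len(clusters)
        counts["clusters_retained"] = len(kept)
        for c, reason in rejected:
            diagnostics.append({"stage": "cluster_filter", "chrom": c.chrom,
                                "pos": c.pos, "reason": reason})

        # --- assembly + partner resolution ---------------------------------------
        candidates: List[_Candidate] = []
        for cluster in kept:
            reads = asm.collect_reads_for_breakpoint(
                cluster, bam, window=config.collect_window, insert_bound=insert_bound)
            if not reads:
                continue
            contigs = asm.assemble_contig(
                reads, min_overlap=config.asm_min_overlap,
                min_identity=config.asm_min_identity)
            rep = max(cluster.members, key=lambda r: (r.clip_len, -r.clip_pos))
            rep_uid = f"{rep.name}/{1 if rep.is_read1 else 2}"
            contig = next((c for c in contigs if rep_uid in c.members), contigs[0])
            res = ga.resolve_partner(cluster, contig, models, index, rcfg)
            if isinstance(res, ga.Rejection):
                diagnostics.append({"stage": "resolve", "chrom": res.chrom,
                                    "pos": res.pos, "reason": res.reason,
                                    "details": res.details})
                continue
            ga.classify_event(res, models, rcfg)
            opp = _nearby_cluster(clusters, res.bp2[0], res.bp2[1],
                                  res.bp2[2], config.cluster_window)
            cand = _Candidate(
                pair=res,
                gene_a="|".join(res.genes_a) or "intergenic",
                gene_b="|".join(res.genes_b) or "intergenic",
                frame=FrameAnnotation("unknown"),
                evidence_reads=tuple(sorted(contig.members)),
                source="softclip",
                support_bp1=cluster.SC_cnt,
                support_bp2=opp.SC_cnt if opp else 0,
            )
            candidates.append(cand)
        counts["pairs_resolved"] = len(candidates)

        # --- splice-junction rescue ------------------------------------------------
        junctions = spl.harvest_novel_junctions(bam.fetch(), models)
        spl.annotate_junction_taf(junctions, depth)
        rescued = spl.rescue_candidates(
            junctions, models, min_span=config.rescue_min_span,
            min_taf=config.rescue_min_taf)
        counts["novel_junctions"] = len(junctions)
        counts["junctions_rescued"] = len(rescued)
        for j in rescued:
            contigs = asm.assemble_contig(
                j.reads, min_overlap=config.asm_min_overlap,
                min_identity=config.asm_min_identity)
            contig = contigs[0]
            pseudo = scl.SoftClipCluster(chrom=j.chrom, pos=j.donor_pos,
                                         clip_side="right", members=[])
            res = ga.resolve_partner(pseudo, contig, models, index, rcfg)
            if isinstance(res, ga.Rejection):
                diagnostics.append({"stage": "rescue_resolve", "chrom": res.chrom,
                                    "pos": res.pos, "reason": res.reason,
                                    "details": res.details})
                continue
            ga.classify_event(res, models, rcfg)
            cand = _Candidate(
                pair=res,
                gene_a="|".join(res.genes_a) or "intergenic",
                gene_b="|".join(res.genes_b) or "intergenic",
                frame=FrameAnnotation("unknown"),
                evidence_reads=tuple(sorted(contig.members)),
                source="splice",
                support_bp1=j.junction_read_cnt,
                support_bp2=j.junction_read_cnt,
            )
            candidates.append(cand)

        # --- merge, frame, score, retain, rank -------------------------------------
        candidates = _merge_candidates(candidates, config.merge_window)
        counts["candidates_merged"] = len(candidates)
        for cand in candidates:
            cand.frame = annotate_frame(cand.pair, models, reference)
            cand.pair.ort = cand.pair.ort  # set by classify_event
            _score_candidate(cand, depth, clusters, read_length, config.area_mode)
        retained, dropped = sc.apply_retention_filters(
            candidates, models, min_score=config.min_fusion_score,
            max_repeat=config.max_repeat, min_taf=config.min_retention_taf)
        for c, reason in dropped:
            diagnostics.append({"stage": "retention", "chrom": c.pair.bp1[0],
                                "pos": c.pair.bp1[1], "reason": reason})
        ranked = sc.grade_and_rank(retained, models, raw_mode=config.raw_mode)
        counts["retained"] = len(ranked)
        logger.info("stage counts: %s", counts)

        rows = [sc.candidate_row(c, config.sample) for c in ranked]
        table = pd.DataFrame(rows, columns=sc.OUTPUT_COLUMNS)
        out_path = out_dir / "fusions.tsv"
        table.to_csv(out_path, sep="\t", index=False)
        diag = pd.DataFrame(diagnostics,
                            columns=["stage", "chrom", "pos", "reason", "details"])
        diag.to_csv(out_dir / "rejected.tsv", sep="\t", index=False)
        config.to_yaml(out_dir / "config.yaml")
        return PipelineResult(candidates=ranked, table=table, counts=counts,
                              output_path=out_path)
    finally:
        logger.removeHandler(handler)
        handler.close()
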