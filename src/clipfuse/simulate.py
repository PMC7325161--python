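"""Synthetic genome, gene models, and planted-fusion read sets.

Generates a two-contig genome (under 50 kb) carrying multi-exon genes with
valid open reading frames, an intergenic enhancer region, and a duplicated
segment for testing paralogous mapping.  Paired-end read sets (100 bp by
default, error-free unless a substitution rate is requested) are emitted
for five planted event classes: a highly expressed exon-to-exon fusion, a
lowly expressed fusion, a non-canonical fusion into the intergenic enhancer
with a non-templated insertion, an internal tandem duplication inside an
ITD-prone kinase gene, and a deletion whose junction reads are spliced (N
CIGAR) rather than clipped.  A truth table records the planted breakpoints
and frame status for end-to-end recovery checks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .genemodel import (
    DEFAULT_ITD_GENES,
    GeneModelSet,
    TranscriptModel,
    load_gene_model,
    revcomp,
    translate_dna,
    write_refflat,
)

logger = logging.getLogger("clipfuse")

READ_LEN = 100
FRAG_LEN = 250

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _rand_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random stop-free codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _rand_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


@dataclass
class _GenePlan:
    name: str
    chrom: str
    strand: str
    start: int
    exon_lens: tuple
    intron_lens: tuple
    utr5: int = 40
    utr3: int = 40


# fixed layout: coordinates chosen so fusion partners sit on both contigs,
# the deletion pair is >10 kb apart, and everything fits in <50 kb total
_LAYOUT = [
    _GenePlan("GENE_A", "chr1", "+", 1500, (260, 300, 260), (160, 180)),
    _GenePlan("GENE_B", "chr2", "+", 1800, (260, 300, 260), (170, 150)),
    _GenePlan("FLT3", "chr1", "+", 4600, (240, 420, 240), (150, 170)),
    _GenePlan("GENE_D1", "chr1", "+", 8200, (260, 300), (160,)),
    _GenePlan("GENE_D2", "chr1", "+", 24600, (260, 300), (150,)),
    _GenePlan("GENE_L", "chr1", "+", 13200, (260, 300), (170,)),
    _GenePlan("GENE_C", "chr2", "+", 5200, (260, 300), (160,)),
    _GenePlan("GENE_O", "chr1", "+", 28600, (260, 300), (150,)),
    _GenePlan("GENE_M", "chr2", "-", 8200, (240, 280), (150,)),
]

CHROM_LENS = {"chr1": 31000, "chr2": 15500}
ENHANCER = ("chr2", 11800, 12400)  # intergenic regulatory region
# duplicated segment: a 400 bp block copied between the contigs
DUP_SRC = ("chr1", 21800, 22200)
DUP_DST = ("chr2", 13600, 14000)
# paralog/IG-analog blacklist shipped with the fixtures
BLACKLIST_REGIONS = [
    ("chr2", 13600, 14000),   # duplicated block
    ("chr2", 14400, 15000),   # V(D)J-style locus analog
]
KNOWN_FUSIONS = [("GENE_A", "GENE_B")]
FUSION_BLACKLIST = [("GENE_X", "GENE_Y")]


def _build_gene(rng, plan: _GenePlan):
    """Returns (genomic segment, TranscriptModel in genome coords, protein)."""
    mrna_len = sum(plan.exon_lens)
    cds_len = mrna_len - plan.utr5 - plan.utr3
    cds_len -= cds_len % 3
    cds = _rand_cds(rng, cds_len // 3)
    mrna = _rand_seq(rng, plan.utr5) + cds + _rand_seq(rng, mrna_len - plan.utr5 - len(cds))
    protein = translate_dna(cds).rstrip("*")

    # slice mRNA into exons, interleave introns (on the transcript strand)
    exon_seqs, off = [], 0
    for ln in plan.exon_lens:
        exon_seqs.append(mrna[off:off + ln])
        off += ln
    introns = [_rand_seq(rng, ln) for ln in plan.intron_lens]
    seg_parts, exon_rel = [], []
    pos = 0
    for i, es in enumerate(exon_seqs):
        exon_rel.append((pos, pos + len(es)))
        seg_parts.append(es)
        pos += len(es)
        if i < len(introns):
            seg_parts.append(introns[i])
            pos += len(introns[i])
    segment = "".join(seg_parts)
    cds_rel = (plan.utr5, plan.utr5 + len(cds))

    def tx_to_rel(t):  # transcript offset -> segment offset (plus orientation)
        for (a, b), (ea, eb) in zip(exon_rel, _cum(plan.exon_lens)):
            if ea <= t < eb:
                return a + (t - ea)
        raise ValueError(t)

    cds_rel_g = (tx_to_rel(cds_rel[0]), tx_to_rel(cds_rel[1] - 1) + 1)

    if plan.strand == "-":
        L = len(segment)
        segment = revcomp(segment)
        exon_rel = [(L - b, L - a) for a, b in reversed(exon_rel)]
        cds_rel_g = (L - cds_rel_g[1], L - cds_rel_g[0])

    exons = tuple((plan.start + a, plan.start + b) for a, b in exon_rel)
    t = TranscriptModel(
        name=f"{plan.name}.1", gene=plan.name, chrom=plan.chrom, strand=plan.strand,
        exons=exons, cds_start=plan.start + cds_rel_g[0], cds_end=plan.start + cds_rel_g[1],
        protein=protein,
    )
    return segment, t, protein


def _cum(lens):
    out, off = [], 0
    for ln in lens:
        out.append((off, off + ln))
        off += ln
    return out


def generate_reference_and_genes(n_genes: int = 9, seed: int = 1):
    """Synthetic genome and gene models.

    Returns (chromosomes: dict name->seq, transcripts, proteins: dict).
    The first ``n_genes`` genes of the fixed layout are emitted; the full
    default roster is required for the planted-fusion read sets.
    """
    if n_genes < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(seed)
    chroms = {c: list(_rand_seq(rng, n)) for c, n in CHROM_LENS.items()}
    transcripts, proteins = [], {}
    for plan in _LAYOUT[:n_genes]:
        seg, t, prot = _build_gene(rng, plan)
        chroms[plan.chrom][plan.start:plan.start + len(seg)] = list(seg)
        transcripts.append(t)
        proteins[t.name] = prot
    genome = {c: "".join(s) for c, s in chroms.items()}
    # plant the duplicated block
    src = genome[DUP_SRC[0]][DUP_SRC[1]:DUP_SRC[2]]
    dst = list(genome[DUP_DST[0]])
    dst[DUP_DST[1]:DUP_DST[2]] = list(src)
    genome[DUP_DST[0]] = "".join(dst)
    transcripts.sort(key=lambda t: (t.chrom, t.tx_start))
    return genome, transcripts, proteins


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class FusionEventSpec:
    """One planted fusion event and its read evidence.

    ``pos_a`` is the donor breakpoint (bases before it retained, clips on
    the right side); ``pos_b`` the acceptor (bases from it retained).  For
    an ITD both lie in the same gene with ``pos_b`` upstream of ``pos_a``.
    """
    name: str
    fclass: str  # 'exon-exon' | 'lowly-expressed' | 'intergenic' | 'ITD' | 'deletion-splice'
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    insertion: str = ""
    n_clip_a: int = 5
    n_clip_b: int = 5
    n_discordant: int = 2
    n_unmapped_mate: int = 1
    n_junction: int = 0          # spliced (N op) junction reads
    bg_depth: int = 30           # background coverage over partner gene exons
    in_frame: Optional[bool] = True
    flank: int = 220


class SamBuilder:
    """Accumulates alignment records and writes sorted SAM/BAM."""

    def __init__(self, genome: Dict[str, str]):
        self.header = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in sorted(genome.items())],
        })
        self.recs: List[pysam.AlignedSegment] = []

    def _tid(self, chrom):
        return self.header.get_tid(chrom)

    def add(self, name, chrom, pos, cigar, seq, mate_chrom=None, mate_pos=None,
            read2=False, mate_unmapped=False, unmapped=False, reverse=False,
            mate_reverse=False, proper=False, tlen=0):
        a = pysam.AlignedSegment(self.header)
        a.query_name = name
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        flag = 0x1  # paired
        flag |= 0x80 if read2 else 0x40
        if unmapped:
            flag |= 0x4
        if mate_unmapped:
            flag |= 0x8
        if reverse:
            flag |= 0x10
        if mate_reverse:
            flag |= 0x20
        if proper:
            flag |= 0x2
        a.flag = flag
        a.reference_id = self._tid(chrom)
        a.reference_start = pos
        a.mapping_quality = 0 if unmapped else 60
        if not unmapped:
            a.cigarstring = cigar
        a.next_reference_id = self._tid(mate_chrom) if mate_chrom else self._tid(chrom)
        a.next_reference_start = mate_pos if mate_pos is not None else pos
        a.template_length = tlen
        self.recs.append(a)

    def write(self, sam_path: Path, make_bam: bool = True) -> Optional[Path]:
        self.recs.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag))
        with pysam.AlignmentFile(str(sam_path), "wh", header=self.header) as fh:
            for r in self.recs:
                fh.write(r)
        if not make_bam:
            return None
        bam_path = sam_path.with_suffix(".bam")
        pysam.sort("-o", str(bam_path), str(sam_path))
        pysam.index(str(bam_path))
        return bam_path


def _apply_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def simulate_fusion_reads(
    spec: FusionEventSpec,
    genome: Dict[str, str],
    models: GeneModelSet,
    builder: SamBuilder,
    rng: np.random.Generator,
    error_rate: float = 0.0,
) -> dict:
    """Emit the read evidence for one planted event into ``builder``.

    Junction-spanning reads are soft-clipped exactly at the planted
    breakpoints (or carry an N operation for the deletion-splice class);
    discordant pairs bracket the junction; pairs with an unmapped mate
    carry the junction (and any non-templated insertion) in the unmapped
    sequence.  Returns the truth-table row for the event.
    """
    ca, pa, cb, pb = spec.chrom_a, spec.pos_a, spec.chrom_b, spec.pos_b
    if not (0 < pa <= len(genome[ca])) or not (0 <= pb < len(genome[cb])):
        raise ValueError("junction out of reference bounds")
    fl = spec.flank
    part_a = genome[ca][pa - fl:pa]
    part_b = genome[cb][pb:pb + fl]
    fusion = part_a + spec.insertion + part_b
    j = fl                      # junction index in the fusion sequence (end of A)
    jb = fl + len(spec.insertion)

    def emit_pair(name, r1, r2):
        builder.add(name, **r1, mate_chrom=r2["chrom"], mate_pos=r2["pos"])
        builder.add(name, **r2, mate_chrom=r1["chrom"], mate_pos=r1["pos"], read2=True)

    err = lambda s: _apply_errors(rng, s, error_rate)

    if spec.fclass == "deletion-splice":
        for i in range(spec.n_junction):
            m = 35 + (i * 7) % 35   # aligned bases before the junction
            seq = err(fusion[j - m:j - m + READ_LEN])
            gap = pb - pa
            cig = f"{m}M{gap}N{READ_LEN - m}M"
            r1 = dict(chrom=ca, pos=pa - m, cigar=cig, seq=seq)
            mpos = max(0, pa - m - FRAG_LEN + READ_LEN)
            r2 = dict(chrom=ca, pos=mpos, cigar=f"{READ_LEN}M",
                      seq=err(genome[ca][mpos:mpos + READ_LEN]), reverse=True)
            emit_pair(f"{spec.name}:jn:{i}", r1, r2)
    else:
        # junction reads anchored on the A side (right clip at pos_a)
        for i in range(spec.n_clip_a):
            m = 40 + (i * 6) % 30
            seq = err(fusion[j - m:j - m + READ_LEN])
            r1 = dict(chrom=ca, pos=pa - m, cigar=f"{m}M{READ_LEN - m}S", seq=seq)
            mpos = max(0, pa - m - FRAG_LEN + READ_LEN)
            r2 = dict(chrom=ca, pos=mpos, cigar=f"{READ_LEN}M",
                      seq=err(genome[ca][mpos:mpos + READ_LEN]), reverse=True)
            emit_pair(f"{spec.name}:clipA:{i}", r1, r2)
        # junction reads anchored on the B side (left clip at pos_b)
        for i in range(spec.n_clip_b):
            s = 40 + (i * 6) % 30   # clipped prefix length
            seq = err(fusion[jb - s:jb - s + READ_LEN])
            r1 = dict(chrom=cb, pos=pb, cigar=f"{s}S{READ_LEN - s}M", seq=seq)
            mpos = min(len(genome[cb]) - READ_LEN, pb + (READ_LEN - s) + FRAG_LEN - 2 * READ_LEN)
            r2 = dict(chrom=cb, pos=mpos, cigar=f"{READ_LEN}M",
                      seq=err(genome[cb][mpos:mpos + READ_LEN]), reverse=True)
            emit_pair(f"{spec.name}:clipB:{i}", r1, r2)
        # discordant pairs bracketing the junction
        for i in range(spec.n_discordant):
            o1 = READ_LEN + 20 + 11 * i
            p1 = max(0, pa - o1)
            p2 = pb + 10 + 9 * i
            r1 = dict(chrom=ca, pos=p1, cigar=f"{READ_LEN}M",
                      seq=err(genome[ca][p1:p1 + READ_LEN]))
            r2 = dict(chrom=cb, pos=p2, cigar=f"{READ_LEN}M",
                      seq=err(genome[cb][p2:p2 + READ_LEN]), reverse=True)
            emit_pair(f"{spec.name}:disc:{i}", r1, r2)
        # anchored read + unmapped mate spanning the junction
        for i in range(spec.n_unmapped_mate):
            p1 = max(0, pa - READ_LEN - 60 - 13 * i)
            off = 45 + 5 * i
            mate_seq = err(fusion[j - off:j - off + READ_LEN])
            builder.add(f"{spec.name}:um:{i}", ca, p1, f"{READ_LEN}M",
                        err(genome[ca][p1:p1 + READ_LEN]),
                        mate_chrom=ca, mate_pos=p1, mate_unmapped=True)
            builder.add(f"{spec.name}:um:{i}", ca, p1, None, mate_seq,
                        mate_chrom=ca, mate_pos=p1, read2=True, unmapped=True)

    # background coverage over the exons of the genic partners
    for chrom, pos in ((ca, pa), (cb, pb)):
        genes = models.genes_at(chrom, pos)
        if genes:
            for g in genes:
                t = models.longest_isoform(g)
                _background_reads(builder, genome, t, spec.bg_depth, spec.name, rng, error_rate)
        else:
            _background_region(builder, genome, chrom, max(0, pos - 150), pos + 150,
                               max(4, spec.bg_depth // 3), spec.name, rng, error_rate)

    frame = {True: "in-frame", False: "out-of-frame", None: "unknown"}[spec.in_frame]
    return {
        "name": spec.name, "class": spec.fclass,
        "chromA": ca, "posA": pa, "chromB": cb, "posB": pb,
        "frame": frame, "insertion_len": len(spec.insertion),
    }


def _background_reads(builder, genome, t: TranscriptModel, depth, tag, rng, error_rate):
    """Concordant proper pairs tiling each exon to the requested coverage."""
    if depth <= 0:
        return
    for ei, (a, b) in enumerate(t.exons):
        if b - a < READ_LEN:
            continue
        n = max(1, round(depth * (b - a) / READ_LEN / 2))  # pairs
        for i in range(n):
            p1 = a + (i * 37) % (b - a - READ_LEN + 1)
            p2 = min(len(genome[t.chrom]) - READ_LEN, p1 + FRAG_LEN - READ_LEN)
            name = f"bg:{tag}:{t.gene}:{ei}:{i}"
            builder.add(name, t.chrom, p1, f"{READ_LEN}M",
                        _apply_errors(rng, genome[t.chrom][p1:p1 + READ_LEN], error_rate),
                        mate_chrom=t.chrom, mate_pos=p2, proper=True,
                        mate_reverse=True, tlen=p2 + READ_LEN - p1)
            builder.add(name, t.chrom, p2, f"{READ_LEN}M",
                        _apply_errors(rng, genome[t.chrom][p2:p2 + READ_LEN], error_rate),
                        mate_chrom=t.chrom, mate_pos=p1, read2=True, proper=True,
                        reverse=True, tlen=-(p2 + READ_LEN - p1))


def _background_region(builder, genome, chrom, a, b, depth, tag, rng, error_rate):
    if depth <= 0:
        return
    if b - a < READ_LEN:
        a = max(0, a - READ_LEN)
    n = max(1, round(depth * max(1, b - a) / READ_LEN / 2))
    for i in range(n):
        p1 = a + (i * 29) % max(1, b - a - READ_LEN + 1)
        p2 = min(len(genome[chrom]) - READ_LEN, p1 + FRAG_LEN - READ_LEN)
        name = f"bg:{tag}:{chrom}:{a}:{i}"
        builder.add(name, chrom, p1, f"{READ_LEN}M",
                    _apply_errors(rng, genome[chrom][p1:p1 + READ_LEN], error_rate),
                    mate_chrom=chrom, mate_pos=p2, proper=True, mate_reverse=True,
                    tlen=p2 + READ_LEN - p1)
        builder.add(name, chrom, p2, f"{READ_LEN}M",
                    _apply_errors(rng, genome[chrom][p2:p2 + READ_LEN], error_rate),
                    mate_chrom=chrom, mate_pos=p1, read2=True, proper=True,
                    reverse=True, tlen=-(p2 + READ_LEN - p1))


# ---------------------------------------------------------------------------
# Default planted events
# ---------------------------------------------------------------------------

def codon_boundary_pos(t: TranscriptModel, exon_index: int, min_into_exon: int = 90) -> int:
    """A genomic position inside the given exon, on a codon boundary.

    Retaining bases strictly before (donor) or from (acceptor) the returned
    position cuts the CDS exactly between codons, so two such breakpoints
    joined without insertion preserve reading frame.
    """
    a, b = t.exons[exon_index]
    cds = t.cds_tx()
    for pos in range(a + min_into_exon, b - min_into_exon):
        tx = t.genomic_to_tx(pos)
        if tx is not None and tx > cds[0] and (tx - cds[0]) % 3 == 0:
            return pos
    raise ValueError("no codon boundary found in exon")


def _safe_insertion(genome, chrom_a, pos_a, chrom_b, pos_b, length: int = 8) -> str:
    """A non-templated insertion with no microhomology at either junction edge.

    The first base differs from the reference base at the donor breakpoint
    and the last from the base preceding the acceptor, so local alignment of
    the fusion contig cannot extend across the junction and the recovered
    breakpoints stay exactly at the planted coordinates.
    """
    first = next(b for b in "ACGT" if b != genome[chrom_a][pos_a])
    last = next(b for b in "ACGT" if b != genome[chrom_b][pos_b - 1])
    middle = ("GTCAGT" * length)[: length - 2]
    return first + middle + last


def default_event_specs(models: GeneModelSet,
                        genome: Optional[Dict[str, str]] = None) -> List[FusionEventSpec]:
    """The five planted study conditions used throughout the test suite."""
    t = {g: models.longest_isoform(g) for g in
         ("GENE_A", "GENE_B", "FLT3", "GENE_D1", "GENE_D2", "GENE_L", "GENE_C", "GENE_O")}
    specs = []
    # 1. highly expressed exon-to-exon fusion, known pair -> HQ
    specs.append(FusionEventSpec(
        name="AB", fclass="exon-exon",
        chrom_a="chr1", pos_a=codon_boundary_pos(t["GENE_A"], 1),
        chrom_b="chr2", pos_b=codon_boundary_pos(t["GENE_B"], 1),
        n_clip_a=4, n_clip_b=3, n_discordant=2, n_unmapped_mate=1, bg_depth=30,
        in_frame=True,
    ))
    # 2. lowly expressed exon-to-exon fusion (novel -> LQ)
    specs.append(FusionEventSpec(
        name="LC", fclass="lowly-expressed",
        chrom_a="chr1", pos_a=codon_boundary_pos(t["GENE_L"], 1),
        chrom_b="chr2", pos_b=codon_boundary_pos(t["GENE_C"], 1),
        n_clip_a=3, n_clip_b=3, n_discordant=1, n_unmapped_mate=0, bg_depth=8,
        in_frame=True,
    ))
    # 3. non-canonical fusion into the intergenic enhancer, 8 bp insertion
    oe_a = codon_boundary_pos(t["GENE_O"], 1)
    oe_b = ENHANCER[1] + 200
    specs.append(FusionEventSpec(
        name="OE", fclass="intergenic",
        chrom_a="chr1", pos_a=oe_a,
        chrom_b=ENHANCER[0], pos_b=oe_b,
        insertion=_safe_insertion(genome, "chr1", oe_a, ENHANCER[0], oe_b)
        if genome else "ACGTTGCA",
        n_clip_a=6, n_clip_b=3, n_discordant=2, n_unmapped_mate=2, bg_depth=25,
        in_frame=None,
    ))
    # 4. 60 bp internal tandem duplication in FLT3 (ITD gene -> HQ)
    flt3 = t["FLT3"]
    dup_start = codon_boundary_pos(flt3, 1, min_into_exon=100)
    specs.append(FusionEventSpec(
        name="ITD", fclass="ITD",
        chrom_a=flt3.chrom, pos_a=dup_start + 60,   # duplication end = donor
        chrom_b=flt3.chrom, pos_b=dup_start,        # re-entry at duplication start
        n_clip_a=5, n_clip_b=0, n_discordant=0, n_unmapped_mate=1, bg_depth=25,
        in_frame=True, flank=200,
    ))
    # 5. ~16 kb deletion producing spliced junction reads (novel -> LQ, high support)
    specs.append(FusionEventSpec(
        name="D1D2", fclass="deletion-splice",
        chrom_a="chr1", pos_a=codon_boundary_pos(t["GENE_D1"], 1),
        chrom_b="chr1", pos_b=codon_boundary_pos(t["GENE_D2"], 0),
        n_junction=12, bg_depth=20,
        in_frame=True,
    ))
    return specs


def write_fixture_set(
    out_dir,
    seed: int = 1,
    classes: Optional[Sequence[str]] = None,
    error_rate: float = 0.0,
    make_bam: bool = True,
) -> dict:
    """Generate the complete fixture bundle into ``out_dir``.

    Writes FASTA (+ .fai), refFlat, protein table, sorted SAM (+ BAM/index),
    knowledge lists, and the truth table.  Returns a dict of paths plus the
    in-memory genome and models.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, transcripts, proteins = generate_reference_and_genes(seed=seed)

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for c in sorted(genome):
            fh.write(f">{c}\n")
            s = genome[c]
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")
    import pyfaidx
    pyfaidx.Faidx(str(fasta))

    refflat = out / "genes.refflat"
    write_refflat(transcripts, refflat)
    prot_path = out / "proteins.tsv"
    with open(prot_path, "w") as fh:
        for name in sorted(proteins):
            fh.write(f"{name}\t{proteins[name]}\n")
    kf_path = out / "known_fusions.tsv"
    with open(kf_path, "w") as fh:
        for a, b in KNOWN_FUSIONS:
            fh.write(f"{a}\t{b}\n")
    itd_path = out / "itd_genes.tsv"
    with open(itd_path, "w") as fh:
        for g in sorted(DEFAULT_ITD_GENES):
            fh.write(g + "\n")
    bl_path = out / "blacklist.bed"
    with open(bl_path, "w") as fh:
        for c, a, b in BLACKLIST_REGIONS:
            fh.write(f"{c}\t{a}\t{b}\n")
    fbl_path = out / "fusion_blacklist.tsv"
    with open(fbl_path, "w") as fh:
        for a, b in FUSION_BLACKLIST:
            fh.write(f"{a}\t{b}\n")

    models = load_gene_model(
        refflat, genome, proteins=proteins,
        known_fusions=KNOWN_FUSIONS, blacklist_regions=BLACKLIST_REGIONS,
        fusion_blacklist=FUSION_BLACKLIST,
    )
    specs = default_event_specs(models, genome)
    if classes is not None:
        specs = [s for s in specs if s.fclass in set(classes)]

    rng = np.random.default_rng(seed + 1)
    builder = SamBuilder(genome)
    truth = [simulate_fusion_reads(s, genome, models, builder, rng, error_rate)
             for s in specs]
    sam = out / "reads.sam"
    bam = builder.write(sam, make_bam=make_bam)

    truth_path = out / "truth.tsv"
    cols = ["name", "class", "chromA", "posA", "chromB", "posB", "frame", "insertion_len"]
    with open(truth_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in truth:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    return {
        "fasta": fasta, "refflat": refflat, "proteins": prot_path,
        "known_fusions": kf_path, "itd_genes": itd_path,
        "blacklist": bl_path, "fusion_blacklist": fbl_path,
        "sam": sam, "bam": bam, "truth": truth_path,
        "genome": genome, "models": models, "truth_rows": truth,
    }
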