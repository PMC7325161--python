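"""Reading-frame annotation of fusion contigs.

The contig is translated in all reading frames (three per strand) and each
partner gene is anchored to a frame by searching for a short amino-acid
tuple taken from the partner transcript: for the 3' partner (gene B) the
tuple is the peptide immediately downstream of the breakpoint, walking into
the transcript until coding sequence is reached and synthesizing in-phase
codons through the 5' UTR when the breakpoint precedes the CDS; for the 5'
partner (gene A) it is the peptide immediately upstream.  The default tuple
is 10 amino acids, grown when the match is ambiguous and shrunk near
transcript ends.  If the tuple search fails (e.g., a variant inside the
tuple), a protein-level local alignment of the translated frames against
the transcript peptide is used as a fallback, with the contig masked to the
gene-B segment to avoid anchoring to the duplicated copy in internal
events.  A fusion is in-frame when both partners anchor in the same frame.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from Bio import Align

from .genemodel import GeneModelSet, TranscriptModel, revcomp, translate_dna

logger = logging.getLogger("clipfuse")

TUPLE_SIZE = 10
TUPLE_GROW = 5
TUPLE_MAX = 30
TUPLE_MIN = 4
FALLBACK_MIN_AA = 10


@dataclass
class Anchor:
    transcript: str
    frame_index: int   # 0-2 forward frames, 3-5 reverse-complement frames
    aa_offset: int     # AA distance of the tuple start from the CDS start
    method: str        # 'tuple' | 'alignment'
    tuple_size: int


@dataclass
class FrameAnnotation:
    status: str                      # 'in-frame' | 'out-of-frame' | 'unknown'
    frame_index: Optional[int] = None
    anchor_a: Optional[Anchor] = None
    anchor_b: Optional[Anchor] = None

    @property
    def multiplier(self) -> int:
        return 2 if self.status == "in-frame" else 1


def translate_three_frames(contig: str) -> List[str]:
    """Translations of frames 0, 1, 2 of the contig; stops rendered as '*'."""
    if len(contig) < 3:
        raise ValueError("contig shorter than one codon")
    return [translate_dna(contig[f:]) for f in range(3)]


def translate_six_frames(contig: str) -> List[str]:
    rc = revcomp(contig)
    return translate_three_frames(contig) + translate_three_frames(rc)


def _retained_range(side: str, pos: int) -> Tuple[int, int]:
    """Genomic half-line retained in the fusion product at a breakpoint."""
    big = 1 << 40
    return (pos, big) if side == "left" else (0, pos)


def downstream_peptide(t: TranscriptModel, reference, pos: int, side: str):
    """Peptide read from the breakpoint onward in transcript direction (gene B).

    Translation starts at the first retained transcript base rounded up to
    CDS phase; positions before the CDS yield synthetic 5'-UTR codons.
    Returns (peptide, aa_offset) or None when nothing is retained.
    """
    cds = t.cds_tx()
    if cds is None:
        return None
    lo, hi = _retained_range(side, pos)
    r = t.tx_range_in(lo, hi)
    if r is None:
        return None
    t0 = r[0]
    start = t0 + ((cds[0] - t0) % 3)
    seq = t.spliced_seq(reference)
    pep = translate_dna(seq[start:])
    if not pep:
        return None
    return pep, (start - cds[0]) // 3


def upstream_peptide(t: TranscriptModel, reference, pos: int, side: str):
    """Peptide ending at the breakpoint, in CDS phase (gene A).

    Returns (peptide, aa_offset_of_end) or None.  The peptide extends up to
    ``TUPLE_MAX`` codons upstream, synthesizing codons into the 5' UTR when
    the CDS alone is too short.
    """
    cds = t.cds_tx()
    if cds is None:
        return None
    lo, hi = _retained_range(side, pos)
    r = t.tx_range_in(lo, hi)
    if r is None:
        return None
    t_excl = r[1] + 1
    end = t_excl - ((t_excl - cds[0]) % 3)
    start = end - 3 * (TUPLE_MAX + 2)
    if start < 0:
        start += 3 * ((2 - start) // 3)
    if end - start < 3:
        return None
    seq = t.spliced_seq(reference)
    pep = translate_dna(seq[start:end])
    if not pep:
        return None
    return pep, (end - cds[0]) // 3


def _frames_containing(frames: Sequence[str], tup: str) -> List[int]:
    return [i for i, f in enumerate(frames) if tup in f]


def _anchor_tuple(frames: Sequence[str], pep: str, from_end: bool):
    """Search a peptide tuple in the frames, growing it until unique.

    Returns (frame_index, tuple_size) or None.  Tuples shorter than
    ``TUPLE_MIN`` are not attempted.
    """
    avail = len(pep)
    n = min(TUPLE_SIZE, avail)
    if n < TUPLE_MIN:
        return None
    while True:
        tup = pep[-n:] if from_end else pep[:n]
        hits = _frames_containing(frames, tup)
        if len(hits) == 1:
            return hits[0], n
        if not hits:
            return None
        n += TUPLE_GROW
        if n > min(TUPLE_MAX, avail):
            return None


_prot_aligner = Align.PairwiseAligner()
_prot_aligner.mode = "local"
_prot_aligner.match_score = 1
_prot_aligner.mismatch_score = -1
_prot_aligner.open_gap_score = -3
_prot_aligner.extend_gap_score = -3


def _count_identities(aln) -> int:
    a, b = aln.sequences
    n = 0
    for (s1, e1), (s2, e2) in zip(aln.aligned[0], aln.aligned[1]):
        n += sum(1 for x, y in zip(a[s1:e1], b[s2:e2]) if x == y)
    return n


def anchor_by_tuple(
    frames: Sequence[str],
    bp: tuple,  # (chrom, pos, side)
    models: GeneModelSet,
    reference,
    end: str,  # 'B' (downstream) or 'A' (upstream)
) -> List[Anchor]:
    """Tuple-search anchors for every eligible transcript at a breakpoint."""
    chrom, pos, side = bp
    out: List[Anchor] = []
    for t in models.anchor_transcripts(chrom, pos):
        pep = (downstream_peptide if end == "B" else upstream_peptide)(t, reference, pos, side)
        if pep is None:
            continue
        res = _anchor_tuple(frames, pep[0], from_end=(end == "A"))
        if res is not None:
            out.append(Anchor(t.name, res[0], pep[1], "tuple", res[1]))
    return out


def anchor_fallback(
    contig: str,
    geneB_qinterval: Tuple[int, int],
    bp: tuple,
    models: GeneModelSet,
    reference,
    min_aa: int = FALLBACK_MIN_AA,
) -> List[Anchor]:
    """Protein-alignment anchoring when the tuple search fails.

    The contig is masked to the gene-B query interval before translation so
    internal events cannot anchor to the upstream duplicate copy; each
    translated frame is locally aligned against the transcript peptide and
    a frame qualifies with >= ``min_aa`` identical aligned residues.
    """
    qs, qe = geneB_qinterval
    masked = "N" * qs + contig[qs:qe] + "N" * (len(contig) - qe)
    frames = translate_six_frames(masked)
    chrom, pos, side = bp
    out: List[Anchor] = []
    for t in models.anchor_transcripts(chrom, pos):
        pep = downstream_peptide(t, reference, pos, side)
        if pep is None:
            continue
        target = pep[0][: TUPLE_MAX * 2]
        best = None
        for i, f in enumerate(frames):
            if len(f) < min_aa:
                continue
            alns = _prot_aligner.align(f, target)
            if not alns:
                continue
            ident = _count_identities(alns[0])
            if ident >= min_aa and (best is None or ident > best[0]):
                best = (ident, i)
        if best is not None:
            out.append(Anchor(t.name, best[1], pep[1], "alignment", min_aa))
    return out


def _donor_compatible(bp: tuple, models: GeneModelSet) -> Optional[bool]:
    """Whether the retained side at this breakpoint is the gene's 5' portion."""
    chrom, pos, side = bp
    genes = models.genes_at(chrom, pos)
    if not genes:
        return None
    votes = {(side == "right") == (models.longest_isoform(g).strand == "+") for g in genes}
    if votes == {True}:
        return True
    if votes == {False}:
        return False
    return None


def annotate_frame(pair, models: GeneModelSet, reference) -> FrameAnnotation:
    """Frame status of a resolved breakpoint pair.

    The 5' partner (gene A) is the breakpoint whose retained side is
    upstream in its gene's transcription direction, falling back to the
    contig prefix segment when orientation is uninformative.  Gene B is
    anchored first, with the alignment fallback, then gene A's upstream
    tuple must land in a compatible frame.  Missing anchors (e.g., an
    intergenic partner) give status ``unknown``.
    """
    contig = pair.contig.seq
    jq = pair.junction_q
    d1 = _donor_compatible(pair.bp1, models)
    d2 = _donor_compatible(pair.bp2, models)
    if d1 is True and d2 is not True:
        bp_a, bp_b = pair.bp1, pair.bp2
    elif d2 is True and d1 is not True:
        bp_a, bp_b = pair.bp2, pair.bp1
    else:
        bp_a, bp_b = (pair.bp1, pair.bp2) if pair.bp1_owns_prefix else (pair.bp2, pair.bp1)
    seg_bp1 = (0, jq) if pair.bp1_owns_prefix else (jq, len(contig))
    seg_bp2 = (jq, len(contig)) if pair.bp1_owns_prefix else (0, jq)
    b_interval = seg_bp1 if bp_b is pair.bp1 else seg_bp2
    frames = translate_six_frames(contig)

    anchors_b = anchor_by_tuple(frames, bp_b, models, reference, end="B")
    if not anchors_b:
        anchors_b = anchor_fallback(contig, b_interval, bp_b, models, reference)
    anchors_a = anchor_by_tuple(frames, bp_a, models, reference, end="A")

    fa = {a.frame_index for a in anchors_a}
    fb = {b.frame_index for b in anchors_b}
    common = fa & fb
    if common:
        fi = min(common)
        return FrameAnnotation(
            "in-frame", fi,
            next(a for a in anchors_a if a.frame_index == fi),
            next(b for b in anchors_b if b.frame_index == fi),
        )
    if fa and fb:
        return FrameAnnotation("out-of-frame", None,
                               anchors_a[0] if anchors_a else None,
                               anchors_b[0] if anchors_b else None)
    return FrameAnnotation("unknown", None,
                           anchors_a[0] if anchors_a else None,
                           anchors_b[0] if anchors_b else None)
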