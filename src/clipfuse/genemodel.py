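"""Reference gene models.

Loads refFlat (genePred, 11 column) transcript annotations against an indexed
FASTA, verifies that annotated CDS intervals actually translate to the
expected protein product, and classifies genomic positions as genic or
intergenic.  All coordinates are 0-based half-open, the native refFlat
convention; every I/O boundary in this package uses the same convention.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

logger = logging.getLogger("clipfuse")

#: Genes with recurrent internal tandem duplications; events inside these
#: genes are graded as high quality even without a known fusion-pair match.
DEFAULT_ITD_GENES = frozenset(
    {"FGFR1", "FLT3", "PDGFRA", "NOTCH1", "EGFR", "PIK3R1", "BRAF", "BCOR", "MYC"}
)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def fetch_seq(reference, chrom: str, start: int, end: int) -> str:
    """Fetch a reference slice from a pyfaidx Fasta or a plain dict of strings."""
    start = max(0, start)
    piece = reference[chrom][start:end]
    return str(getattr(piece, "seq", piece)).upper()


def translate_dna(seq: str) -> str:
    """Standard-code translation; any codon containing a non-ACGT base -> 'X'."""
    clean = "".join(c if c in "ACGT" else "N" for c in seq.upper())
    n = len(clean) - len(clean) % 3
    if n <= 0:
        return ""
    return str(Seq(clean[:n]).translate())


@dataclass
class TranscriptModel:
    """One refFlat transcript: exon structure, CDS bounds, expected protein."""

    name: str
    gene: str
    chrom: str
    strand: str
    exons: tuple  # ordered, non-overlapping [start, end) genomic intervals
    cds_start: int
    cds_end: int
    protein: Optional[str] = None
    verified: Optional[bool] = None  # None = not checked / no protein on file
    mismatch_fraction: Optional[float] = None

    def __post_init__(self):
        ex = tuple((int(a), int(b)) for a, b in self.exons)
        if any(b <= a for a, b in ex):
            raise ValueError(f"{self.name}: empty or inverted exon")
        for (a1, b1), (a2, b2) in zip(ex, ex[1:]):
            if a2 < b1:
                raise ValueError(f"{self.name}: exons overlap or are unsorted")
        self.exons = ex
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: bad strand {self.strand!r}")
        if self.has_cds and not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
            raise ValueError(f"{self.name}: CDS outside transcript span")

    # -- spans ------------------------------------------------------------
    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def has_cds(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def mRNA_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    # -- coordinate mapping ------------------------------------------------
    def _plus_offset(self, pos: int) -> Optional[int]:
        """Offset of an exonic genomic position in the plus-strand spliced mRNA."""
        off = 0
        for a, b in self.exons:
            if a <= pos < b:
                return off + (pos - a)
            off += b - a
        return None

    def genomic_to_tx(self, pos: int) -> Optional[int]:
        """Transcript (coding-strand) coordinate of an exonic genomic position."""
        off = self._plus_offset(pos)
        if off is None:
            return None
        return off if self.strand == "+" else self.mRNA_length - 1 - off

    def tx_range_in(self, lo: int, hi: int) -> Optional[tuple]:
        """Min/max transcript coordinates of exonic bases inside genomic [lo, hi)."""
        tmin = tmax = None
        off = 0
        for a, b in self.exons:
            s, e = max(a, lo), min(b, hi)
            if s < e:
                p1 = off + (s - a)
                p2 = off + (e - 1 - a)
                if self.strand == "-":
                    L = self.mRNA_length
                    p1, p2 = L - 1 - p2, L - 1 - p1
                tmin = p1 if tmin is None else min(tmin, p1)
                tmax = p2 if tmax is None else max(tmax, p2)
            off += b - a
        return None if tmin is None else (tmin, tmax)

    def cds_tx(self) -> Optional[tuple]:
        """CDS as a [start, end) interval in transcript coordinates."""
        if not self.has_cds:
            return None
        r = self.tx_range_in(self.cds_start, self.cds_end)
        if r is None:
            return None
        return r[0], r[1] + 1

    # -- sequence ----------------------------------------------------------
    def spliced_seq(self, reference) -> str:
        s = "".join(fetch_seq(reference, self.chrom, a, b) for a, b in self.exons)
        return s if self.strand == "+" else revcomp(s)

    def cds_seq(self, reference) -> str:
        pieces = []
        for a, b in self.exons:
            s, e = max(a, self.cds_start), min(b, self.cds_end)
            if s < e:
                pieces.append(fetch_seq(reference, self.chrom, s, e))
        s = "".join(pieces)
        return s if self.strand == "+" else revcomp(s)


@dataclass
class LocusClass:
    genic: bool
    genes: tuple = ()


@dataclass
class TranslationCheck:
    passed: bool
    mismatch_fraction: float
    reason: str = ""


def verify_coding_translation(t: TranscriptModel, reference) -> TranslationCheck:
    """De novo translate the spliced CDS and compare with the expected protein.

    Mismatches are counted position-wise over the shorter of the two
    sequences, with any length difference added as further mismatches; the
    fraction is taken over the longer sequence.  At most 4% mismatch passes.
    """
    if not t.has_cds or not t.protein:
        raise ValueError(f"{t.name}: transcript lacks CDS or expected protein")
    cds = t.cds_seq(reference)
    if len(cds) % 3 != 0:
        return TranslationCheck(False, 1.0, "incomplete CDS")
    aa = translate_dna(cds).rstrip("*")
    exp = t.protein.rstrip("*")
    mism = sum(a != b for a, b in zip(aa, exp)) + abs(len(aa) - len(exp))
    frac = mism / max(len(aa), len(exp), 1)
    return TranslationCheck(frac <= 0.04, frac)


@dataclass
class GeneModelSet:
    """Transcript collection with a positional index and knowledge lists."""

    transcripts: list
    blacklist_regions: list = field(default_factory=list)  # (chrom, start, end)
    known_fusions: set = field(default_factory=set)  # frozenset gene pairs
    itd_genes: set = field(default_factory=lambda: set(DEFAULT_ITD_GENES))
    fusion_blacklist: set = field(default_factory=set)  # frozenset gene pairs

    def __post_init__(self):
        self._trees: dict = {}
        self.by_gene: dict = {}
        for t in self.transcripts:
            self._trees.setdefault(t.chrom, IntervalTree()).addi(t.tx_start, t.tx_end, t)
            self.by_gene.setdefault(t.gene, []).append(t)
        # gene spans (union over isoforms) for neighbor lookup
        self._gene_span = {}
        for g, ts in self.by_gene.items():
            self._gene_span[g] = (
                ts[0].chrom,
                min(t.tx_start for t in ts),
                max(t.tx_end for t in ts),
                ts[0].strand,
            )

    def __len__(self):
        return len(self.transcripts)

    # -- positional queries --------------------------------------------------
    def transcripts_at(self, chrom: str, pos: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda t: (-t.mRNA_length, t.name))

    def genes_at(self, chrom: str, pos: int) -> tuple:
        return tuple(sorted({t.gene for t in self.transcripts_at(chrom, pos)}))

    def anchor_transcripts(self, chrom: str, pos: int) -> list:
        """CDS-bearing transcripts at a position, excluding failed translations."""
        return [t for t in self.transcripts_at(chrom, pos) if t.has_cds and t.verified is not False]

    def longest_isoform(self, gene: str) -> Optional[TranscriptModel]:
        ts = self.by_gene.get(gene)
        if not ts:
            return None
        return max(ts, key=lambda t: (t.mRNA_length, t.name))

    # -- knowledge lists -------------------------------------------------------
    def in_blacklist(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and a <= pos < b for c, a, b in self.blacklist_regions)

    def is_known_fusion(self, gene_a: str, gene_b: str) -> bool:
        return frozenset((gene_a, gene_b)) in self.known_fusions

    def pair_blacklisted(self, gene_a: str, gene_b: str) -> bool:
        return frozenset((gene_a, gene_b)) in self.fusion_blacklist

    def downstream_neighbor(self, gene: str):
        """Nearest same-strand gene downstream in transcription order, with distance."""
        span = self._gene_span.get(gene)
        if span is None:
            return None
        chrom, start, end, strand = span
        best = None
        for g, (c, s, e, st) in self._gene_span.items():
            if g == gene or c != chrom or st != strand:
                continue
            if strand == "+" and s >= end:
                d = s - end
            elif strand == "-" and e <= start:
                d = start - e
            else:
                continue
            if best is None or d < best[1] or (d == best[1] and g < best[0]):
                best = (g, d)
        return best


def classify_locus(chrom: str, pos: int, models: GeneModelSet) -> LocusClass:
    """Genic iff pos falls inside the transcription span of >=1 transcript."""
    if chrom not in models._trees:
        logger.warning("classify_locus: unknown chromosome %r; treating as intergenic", chrom)
        return LocusClass(False)
    genes = models.genes_at(chrom, pos)
    return LocusClass(bool(genes), genes) if genes else LocusClass(False)


# ---------------------------------------------------------------------------
# refFlat and auxiliary file I/O
# ---------------------------------------------------------------------------

def parse_refflat(path) -> list:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise ValueError(f"refFlat parse error at line {i}: expected 11 columns, got {len(f)}")
            try:
                starts = [int(x) for x in f[9].rstrip(",").split(",")]
                ends = [int(x) for x in f[10].rstrip(",").split(",")]
                n = int(f[8])
                if len(starts) != n or len(ends) != n:
                    raise ValueError("exonCount disagrees with exon lists")
                t = TranscriptModel(
                    name=f[1], gene=f[0], chrom=f[2], strand=f[3],
                    exons=tuple(zip(starts, ends)),
                    cds_start=int(f[6]), cds_end=int(f[7]),
                )
            except (ValueError, IndexError) as e:
                raise ValueError(f"refFlat parse error at line {i}: {e}") from e
            out.append(t)
    return out


def write_refflat(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            starts = ",".join(str(a) for a, _ in t.exons) + ","
            ends = ",".join(str(b) for _, b in t.exons) + ","
            fh.write("\t".join(map(str, [
                t.gene, t.name, t.chrom, t.strand, t.tx_start, t.tx_end,
                t.cds_start, t.cds_end, len(t.exons), starts, ends,
            ])) + "\n")


def _read_two_col(path) -> list:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows


def load_gene_model(
    refflat_path,
    reference,
    proteins=None,
    known_fusions=None,
    itd_genes=None,
    blacklist_regions=None,
    fusion_blacklist=None,
) -> GeneModelSet:
    """Build a :class:`GeneModelSet` from refFlat + FASTA plus optional lists.

    ``proteins`` maps transcript accession to the expected amino-acid
    sequence (dict or two-column TSV).  Transcripts whose chromosome is not
    present in the FASTA are skipped with a warning.  Each protein-bearing
    transcript is translation-verified; failures are retained in the set but
    excluded from reading-frame anchoring.
    """
    transcripts = parse_refflat(refflat_path)
    names = set(reference.keys()) if hasattr(reference, "keys") else None
    kept = []
    for t in transcripts:
        if names is not None and t.chrom not in names:
            logger.warning("skipping %s: chromosome %r absent from reference", t.name, t.chrom)
            continue
        kept.append(t)

    if proteins is not None and not isinstance(proteins, Mapping):
        rows = _read_two_col(proteins)
        proteins = {r[0]: r[1] for r in rows if len(r) >= 2 and r[0].lower() not in ("name", "transcript")}
    if proteins:
        for t in kept:
            if t.name in proteins and t.has_cds:
                t.protein = proteins[t.name]
                chk = verify_coding_translation(t, reference)
                t.verified = chk.passed
                t.mismatch_fraction = chk.mismatch_fraction
                if not chk.passed:
                    logger.warning(
                        "transcript %s failed translation check (%.3f mismatch%s); "
                        "excluded from frame anchoring",
                        t.name, chk.mismatch_fraction,
                        f"; {chk.reason}" if chk.reason else "",
                    )

    def _pairs(src):
        if src is None:
            return set()
        if isinstance(src, (set, frozenset, list, tuple)):
            return {frozenset(p) for p in src}
        return {frozenset(r[:2]) for r in _read_two_col(src) if len(r) >= 2 and r[0].lower() != "genea"}

    if itd_genes is None:
        itd = set(DEFAULT_ITD_GENES)
    elif isinstance(itd_genes, (set, frozenset, list, tuple)):
        itd = set(itd_genes)
    else:
        itd = {r[0] for r in _read_two_col(itd_genes) if r[0].lower() != "gene"}

    if blacklist_regions is None:
        regions = []
    elif isinstance(blacklist_regions, (list, tuple)):
        regions = [(c, int(a), int(b)) for c, a, b in blacklist_regions]
    else:  # BED path
        regions = [(r[0], int(r[1]), int(r[2])) for r in _read_two_col(blacklist_regions) if len(r) >= 3]

    return GeneModelSet(
        transcripts=kept,
        blacklist_regions=regions,
        known_fusions=_pairs(known_fusions),
        itd_genes=itd,
        fusion_blacklist=_pairs(fusion_blacklist),
    )
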