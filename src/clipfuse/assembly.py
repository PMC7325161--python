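"""Greedy overlap-consensus assembly of junction-informative reads.

For each candidate breakpoint we gather the clipped reads of the cluster,
their mates, discordantly mapped pairs in the surrounding region whose
mapped end could project past the junction, and pairs with one unmapped
mate (the signature of non-templated insertions).  These are assembled into
consensus contigs by greedy best-overlap merging: exact k-mer seeding
proposes an offset between a read and a growing contig, the overlap must be
at least ``min_overlap`` bases at ``min_identity`` identity, and each
consensus column is the majority base over its supporting reads.  Both read
orientations are tried, so mate sequences are implicitly normalized to the
anchored strand.
"""
from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .genemodel import revcomp
from .softclips import SoftClipCluster

logger = logging.getLogger("clipfuse")

_SEED_K = 13


@dataclass
class ReadEvidence:
    uid: str       # read name + mate suffix
    seq: str
    kind: str      # 'sc' | 'mate' | 'discordant' | 'unmapped_mate' | 'junction'


@dataclass
class Contig:
    """A consensus sequence with the placement interval of every member read."""
    seq: str
    members: Dict[str, Tuple[int, int]]  # uid -> [start, end) on the contig
    depth: List[int]                     # per-column read support
    orientations: Dict[str, bool] = field(default_factory=dict)  # uid -> reverse-complemented?

    @property
    def n_members(self) -> int:
        return len(self.members)


class _Work:
    __slots__ = ("cols", "members", "orientations", "_consensus", "_kmers")

    def __init__(self, uid: str, seq: str):
        self.cols = [Counter({b: 1}) for b in seq]
        self.members: Dict[str, Tuple[int, int]] = {uid: (0, len(seq))}
        self.orientations: Dict[str, bool] = {uid: False}
        self._consensus: Optional[str] = None
        self._kmers: Optional[dict] = None

    def consensus(self) -> str:
        if self._consensus is None:
            self._consensus = "".join(
                max(sorted(c), key=lambda b: c[b]) for c in self.cols
            )
        return self._consensus

    def kmers(self) -> dict:
        if self._kmers is None:
            s = self.consensus()
            d: dict = {}
            for i in range(len(s) - _SEED_K + 1):
                d.setdefault(s[i : i + _SEED_K], []).append(i)
            self._kmers = d
        return self._kmers

    def merge(self, uid: str, seq: str, offset: int, is_rc: bool = False) -> None:
        if offset < 0:
            pad = -offset
            self.cols = [Counter() for _ in range(pad)] + self.cols
            self.members = {k: (a + pad, b + pad) for k, (a, b) in self.members.items()}
            offset = 0
        end = offset + len(seq)
        while len(self.cols) < end:
            self.cols.append(Counter())
        for i, b in enumerate(seq):
            self.cols[offset + i][b] += 1
        self.members[uid] = (offset, end)
        self.orientations[uid] = is_rc
        self._consensus = None
        self._kmers = None


def _best_offset(work: _Work, seq: str, min_overlap: int, min_identity: float):
    """Best placement of seq on the working contig; returns (matches, offset)."""
    votes: Counter = Counter()
    km = work.kmers()
    for i in range(0, len(seq) - _SEED_K + 1):
        for j in km.get(seq[i : i + _SEED_K], ()):
            votes[j - i] += 1
    cons = work.consensus()
    best = None
    for offset, _ in votes.most_common(3):
        a = max(0, offset)
        b = min(len(cons), offset + len(seq))
        ov = b - a
        if ov < min_overlap:
            continue
        matches = sum(
            1 for k in range(a, b) if cons[k] == seq[k - offset] and cons[k] != "N"
        )
        if matches / ov < min_identity:
            continue
        if best is None or matches > best[0] or (matches == best[0] and offset < best[1]):
            best = (matches, offset)
    return best


def assemble_contig(
    reads: Sequence, min_overlap: int = 25, min_identity: float = 0.9
) -> List[Contig]:
    """Greedy overlap-consensus assembly; deterministic for any input order.

    ``reads`` is a sequence of (uid, seq) pairs or :class:`ReadEvidence`.
    Reads are processed by descending length then uid; each read joins the
    contig where it achieves the most matching overlap bases (either
    orientation), or founds a new contig.  Singletons are emitted as their
    own contigs.
    """
    items: List[Tuple[str, str]] = []
    for r in reads:
        if isinstance(r, ReadEvidence):
            items.append((r.uid, r.seq.upper()))
        else:
            uid, seq = r[0], r[1]
            items.append((uid, seq.upper()))
    items.sort(key=lambda x: (-len(x[1]), x[0]))

    works: List[_Work] = []
    for uid, seq in items:
        best = None  # (matches, contig index, offset, oriented seq, is_rc)
        for ci, w in enumerate(works):
            for s, is_rc in ((seq, False), (revcomp(seq), True)):
                hit = _best_offset(w, s, min_overlap, min_identity)
                if hit and (best is None or hit[0] > best[0]):
                    best = (hit[0], ci, hit[1], s, is_rc)
        if best is None:
            works.append(_Work(uid, seq))
        else:
            works[best[1]].merge(uid, best[3], best[2], best[4])

    contigs = [
        Contig(
            seq=w.consensus(),
            members=dict(sorted(w.members.items())),
            depth=[sum(c.values()) for c in w.cols],
            orientations=dict(sorted(w.orientations.items())),
        )
        for w in works
    ]
    contigs.sort(key=lambda c: (-c.n_members, -len(c.seq), c.seq))
    return contigs


# ---------------------------------------------------------------------------
# Read collection around a candidate breakpoint
# ---------------------------------------------------------------------------

def estimate_insert_bound(bam, n: int = 10000, default: int = 600) -> int:
    """Fragment-size bound from the first ``n`` proper pairs: median + 3*MAD."""
    sizes = []
    for rec in bam.fetch():
        if rec.is_proper_pair and rec.template_length > 0 and not (rec.flag & 0xF00):
            sizes.append(rec.template_length)
            if len(sizes) >= n:
                break
    if hasattr(bam, "reset"):
        bam.reset()
    if len(sizes) < 50:
        return default
    med = statistics.median(sizes)
    mad = statistics.median(abs(s - med) for s in sizes)
    return int(med + 3 * mad) or default


def _uid(rec) -> str:
    return f"{rec.query_name}/{2 if rec.is_read2 else 1}"


def collect_reads_for_breakpoint(
    bp: SoftClipCluster,
    bam,
    window: int = 1000,
    insert_bound: int = 600,
) -> List[ReadEvidence]:
    """Junction-informative reads for one candidate breakpoint.

    Returns the cluster's soft-clipped reads, their mates, discordant pairs
    in +-``window`` whose mapped read could project past the junction given
    the fragment-size bound, and mapped reads with unmapped mates (plus the
    unmapped mate records themselves).  Concordant clip-free pairs carry no
    junction information and are excluded.
    """
    member_keys = {(r.name, r.is_read1) for r in bp.members}
    mate_coords = {
        (r.mate_chrom, r.mate_pos, r.name, not r.is_read1)
        for r in bp.members
        if r.mate_mapped and r.mate_chrom is not None
    }
    out: Dict[str, ReadEvidence] = {}

    def add(rec, kind):
        uid = _uid(rec)
        if uid not in out and rec.query_sequence:
            out[uid] = ReadEvidence(uid=uid, seq=rec.query_sequence, kind=kind)

    lo, hi = max(0, bp.pos - window), bp.pos + window
    try:
        fetched = list(bam.fetch(bp.chrom, lo, hi))
    except (ValueError, OSError) as e:  # region fetch failure
        logger.warning("skipping breakpoint %s:%d: fetch failed (%s)", bp.chrom, bp.pos, e)
        return []

    for rec in fetched:
        if rec.flag & 0x700:  # secondary/supplementary/duplicate
            continue
        if rec.is_unmapped:
            if rec.is_paired:
                add(rec, "unmapped_mate")
            continue
        key = (rec.query_name, not rec.is_read2)
        if key in member_keys:
            add(rec, "sc")
            continue
        if rec.is_paired and rec.mate_is_unmapped:
            add(rec, "unmapped_mate")
            continue
        if rec.is_paired and not rec.mate_is_unmapped:
            discordant = (
                rec.next_reference_name != rec.reference_name
                or abs(rec.template_length) > insert_bound
                or not rec.is_proper_pair
            )
            if discordant and _projects_past(rec, bp, insert_bound):
                add(rec, "discordant")

    # mates of clipped reads (and of collected discordant reads) by position
    want = set(mate_coords)
    for rec in fetched:
        uid = _uid(rec)
        if uid in out and out[uid].kind == "discordant" and not rec.mate_is_unmapped:
            want.add((rec.next_reference_name, rec.next_reference_start,
                      rec.query_name, rec.is_read2))  # mate is read1 iff rec is read2
    for chrom, pos, name, is_r1 in sorted(want, key=lambda t: (str(t[0]), t[1], t[2])):
        if chrom is None:
            continue
        try:
            for rec in bam.fetch(chrom, max(0, pos), pos + 1):
                if rec.query_name == name and (not rec.is_read2) == is_r1 and not (rec.flag & 0x700):
                    add(rec, "mate")
                    break
        except (ValueError, OSError):
            continue
    return sorted(out.values(), key=lambda r: r.uid)


def _projects_past(rec, bp: SoftClipCluster, insert_bound: int) -> bool:
    """Could the fragment of this mapped read extend across the junction?"""
    if bp.clip_side == "right":
        return rec.reference_start <= bp.pos and bp.pos - rec.reference_start <= insert_bound
    return rec.reference_end >= bp.pos and rec.reference_end - bp.pos <= insert_bound
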