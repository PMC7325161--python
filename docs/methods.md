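# Methods

`clipfuse` calls gene fusions from coordinate-sorted paired-end RNA-seq
alignments by treating fusion junctions as local assembly problems anchored
at soft-clip clusters, then scoring each resolved junction with an
evidence model. This note documents the procedure, its parameters, the
numerical choices, and what the bundled simulations do and do not show.

## Breakpoint discovery

A read whose CIGAR ends in a soft-clip (`S`) marks a putative junction: the
aligner placed part of the read at one locus and gave up on the remainder,
which belongs to the partner. Clips on the same side within 3 bp of one
another are chained (single linkage) into a cluster whose representative
position is the clip position of the member with the longest clipped
subsequence (ties: leftmost). Left- and right-side clips cluster
separately because they represent opposite junction orientations.

A cluster must pass four retention criteria to become a candidate
breakpoint:

1. clip support `SC_cnt ≥ 2` at genic sites, `≥ 5` at intergenic sites
   (genic means anywhere inside a transcription span, introns included,
   so breakpoints at cryptic exons still count as genic);
2. for genic sites, `adjusted_gene_exp = w · read_cnt / mRNA_length ≥ 0.01`
   with `w = (read_length − 20)/100` floored at 0 — short reads are rarely
   soft-clipped, so read-count expression is down-weighted for them;
3. the site is not inside a blacklisted paralogous region;
4. the transcriptional allelic fraction `SC_TAF = SC_cnt / depth` strictly
   exceeds 0.05, where depth is the number of mapped reads overlapping the
   cluster position. A local denominator keeps the quantity an allele
   fraction in (0, 1]; a library-wide denominator would not be one.

Where a cluster overlaps several genes, the expression criterion uses the
maximum over those genes, and `mRNA_length` comes from the longest isoform
(a configurable policy; annotation sets rarely agree on a canonical
isoform).

## Local assembly

For each candidate breakpoint we collect the cluster's clipped reads, their
mates, discordant pairs in ±1 kb whose mapped read lies close enough to the
junction that its fragment could extend across it (the fragment-size bound
is estimated from the first 10,000 proper pairs as median + 3·MAD, default
600 when too few pairs exist), and pairs with one unmapped mate — the
classic signature of non-templated insertions at the junction.

Reads are assembled by greedy overlap consensus: reads are processed by
descending length then name (so the result is independent of input order),
each read is placed on an existing contig at the offset proposed by exact
13-mer seeding if the overlap is ≥ 25 bp at ≥ 0.9 identity (both read
orientations are tried, which normalizes mate orientation), and otherwise
founds a new contig. Each consensus column is the majority base over its
supporting reads, ties broken alphabetically. The assembler records every
member's placement interval and orientation; the junction position on the
contig is later pinned by the representative clipped read's placement,
which is exact by construction and immune to alignment pathologies (see
below). Quality-weighted consensus is not implemented.

## Contig re-alignment and partner resolution

Contigs are mapped back to the reference with an 11-mer seed index and full
local dynamic programming (match +1, mismatch −1, gap −2) inside each
seeded window; a hit's score is the DP score, which approximates a
BLAT-style `matches − penalties`, and hits below score 25 are discarded,
keeping the top 3.

Two rounds are performed. Round one aligns the full contig: the genuine
discovery-side hit must terminate at the clip boundary (right-side clips
align `[x, pos)`, left-side clips `[pos, y)`, with 5 bp slack for
microhomology); if some other locus explains ≥ 95% of the contig
contiguously, the candidate is discarded as a paralogous-mapping artifact.
The contig portion beyond the junction (`s2`) is aligned in round two, and
the partner is chosen by preferring hits in the same gene, then hits within
100 kb, then alignment score — a conservative order that prefers local
events over gross rearrangements. Multi-mapping of `s2` is allowed (it is
what makes fusions in repetitive regions discoverable); it is penalized
through the repeat score, not rejected. Candidates with both breakpoints
inside blacklisted paralog/immunoglobulin-type regions are dropped.

Two numerical details matter for breakpoint exactness:

* the partner breakpoint is the junction-facing boundary of the `s2`
  alignment, never an extrapolation through unaligned `s2` bases (those are
  non-templated insertions); and
* because Smith–Waterman will happily glue a net-positive run of mismatched
  insertion bases onto a true hit, the junction-facing end of the alignment
  is trimmed back until its terminal five columns are exact matches.

An internal tandem duplication presents as a same-gene pair with
duplication geometry (the partner segment re-maps upstream of the
discovery breakpoint on the same strand). Same-strand neighboring genes
joined with deletion geometry within 200 kb are flagged read-through. The
orientation multiplier `ort` is 2 when the contig geometry is consistent
with both partner genes' transcription orientations in either contig
reading direction, else 1; intergenic partners always give 1.

## Splice-junction rescue

Deletion fusions within an aligner's splicing span produce junction reads
with `N` CIGAR operations instead of clips. All `N` junctions absent from
the annotated intron set are harvested; junctions spanning ≥ 10 kb,
touching ≥ 2 distinct genes, with junction-read allelic fraction > 0.01
(same local-depth convention as `SC_TAF`) are converted to candidates. The
junction reads are assembled with the same assembler and flow through the
same partner-resolution, frame and scoring stages; their matched length is
taken as the full read length since junction reads are fully mapped. A
junction also found via soft-clips (both breakpoints within 5 bp) is merged
into the soft-clip candidate, never double-reported. No upper span cap is
imposed; aligner-specific junction tab files are not read.

## Reading-frame annotation

The contig is translated in six frames (three per orientation; an
assembled contig's strand relative to the transcripts is arbitrary). Each
partner is anchored by searching the frames for a short amino-acid tuple
derived from the transcript: for the 3' partner (gene B) the peptide
downstream of the breakpoint, translating from the first retained base
rounded up to CDS phase — positions before the CDS yield synthetic 5'-UTR
codons, which lets promoter-swap breakpoints anchor; for the 5' partner
(gene A) the peptide ending at the breakpoint in CDS phase. The tuple
starts at 10 amino acids, grows by 5 (to at most 30) while it matches more
than one frame, and shrinks near transcript ends (minimum 4). If the tuple
search fails — typically a variant inside the tuple — a protein-level local
alignment of the translated frames against the transcript peptide is used,
requiring ≥ 10 identical aligned residues, with the contig masked to the
gene-B segment so internal events cannot anchor to the upstream duplicate
copy. Transcripts whose annotated CDS does not reproduce the expected
protein within 4% mismatch (counted position-wise, length differences as
mismatches) are excluded from anchoring.

A fusion is in-frame when any gene-A anchor and any gene-B anchor share a
frame index (one compatible isoform pair suffices), out-of-frame when both
partners anchor but never in the same frame, and unknown when either
partner has no anchor (intergenic partners, enhancer hijacking).

## Evidence score, grading, ranking

Each breakpoint *p* contributes

    score_p = w_TAF · w_Match · area · (1 − repeat(p))

with

    w_TAF   = 1                      if TAF ≥ 0.01,  else exp(−0.01/TAF)
    w_Match = 1                      if match_length ≥ 0.5·read_length,
              exp((match_length − 0.5·read_length)/2)  otherwise
    repeat(p) = 1 − matches(p) / Σᵢ matches(pᵢ)

where the sum runs over alignments with > 90% identity that compete for
the same contig segment as *p*'s hit (query-interval overlap ≥ 50%). The
segment restriction is deliberate: pooling the partner segment's hit would
give every clean two-locus fusion a repeat near 0.5, whereas repeat 0 must
mean unique mapping. `area` is the summed length of junction-read
subsequences mapped to the contig, restricted to members whose placement
crosses the junction; a union-of-covered-positions variant is available via
`area_mode="union"`. The same area value enters both breakpoint scores.

The combined score is

    score = 0.5 · (score_p(bp1) + score_p(bp2)) · ort · frame

with `frame` = 2 for in-frame fusions and 1 otherwise. Candidates with
`score ≥ 1`, both repeat scores < 0.7 and both TAFs ≥ 0.01 are retained;
blacklisted gene pairs are removed after scoring so diagnostics keep their
breakdowns. Retained candidates are graded HQ (known fusion pair, or an
ITD event in a known ITD gene — FGFR1, FLT3, PDGFRA, NOTCH1, EGFR, PIK3R1,
BRAF, BCOR, MYC by default), RT (read-through), or LQ, and ranked HQ, LQ,
RT with descending score inside each tier; `--raw` ranks by score alone.
Ties break lexicographically on gene symbols and position so reruns are
byte-identical.

## Synthetic fixtures

The bundled generator builds a two-contig genome (46.5 kb total) carrying
nine multi-exon genes with valid open reading frames (verified at 0%
mismatch by construction), an intergenic enhancer region, a duplicated
400 bp block for paralog tests, and blacklist/known-fusion/ITD lists. Five
events are planted with 100 bp paired-end reads: a highly expressed
exon-to-exon fusion on a known pair (clip support 4+3, ~30× background), a
lowly expressed fusion (3+3, 8×), a fusion into the enhancer with an 8 bp
non-templated insertion (frame unknowable), a 60 bp in-frame ITD in FLT3,
and a ~16 kb deletion emitting 12 spliced junction reads. Junction-spanning
reads are emitted soft-clipped (or `N`-spliced) exactly at the planted
coordinates; insertion bases are chosen to avoid microhomology at the
junction edges so recovered breakpoints are exact for every seed. Reads
are error-free by default with an optional substitution-rate knob.

What the fixtures emulate: clip/discordant/unmapped-mate/spliced evidence
signatures, local depth and allele fractions, expression filtering, frame
arithmetic, knowledge-based grading. What they do not: sequencing-error
profiles, splicing within junction flanks (breakpoints are placed mid-exon
so contigs are exonic), minus-strand fusion partners, isoform complexity,
polyA artifacts, and genome-scale repeat content. Passing the end-to-end
suite therefore demonstrates the machinery is correct under controlled
conditions, not calibrated sensitivity on real tumor libraries.

## Determinism and scale

Runs are single-process and fully deterministic: identical configuration
and inputs give byte-identical output tables. Per-chromosome parallelism
was considered and dropped — at the intended scale (targeted panels,
fixtures, method development) a single pass is fast, and the determinism
contract is simpler to guarantee. The k-mer reference index is held in
memory, which is appropriate for references up to tens of megabases;
whole-human-genome use would need an external aligner behind the same hit
interface. Problem sizes used by the test suite: a 46.5 kb genome, ~350
reads per run, 200-query aligner-oracle sweeps, and 100-trial assembler
reconstructions.

## Known limitations

* `read_cnt` per gene counts primary alignments starting inside the
  transcription span — a cheap proxy for FPKM-style expression, biased for
  heavily overlapping genes.
* The V(D)J exclusion is interval-based (both breakpoints in blacklisted
  loci) rather than a geometric recombination model.
* CAP3's quality-aware parameters (−z/−h/−y) have no analog in the
  majority-vote consensus.
* Frame annotation assumes junction-proximal contig sequence is exonic;
  breakpoints inside introns of the retained partner can defeat the tuple
  search and fall back to alignment anchoring or `unknown`.
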