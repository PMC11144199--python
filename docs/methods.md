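# Methods

## Scope and data flow

`stitchpairs` covers the upstream portion of Hi-C / Micro-C analysis: raw
paired-end FASTQ → trimmed/deduplicated/stitched reads → external local
alignment → filtered chimeric classification → sorted 4DN pairs file. The
aligner itself is out of scope: any local aligner satisfying the split-read
contract below can be plugged in via a command template. Binary `.hic` /
`.cool` generation is delegated to external converters; a Juicer
"short-format" writer is provided as the bridge.

## Simulator

The generative model is intentionally minimal: enough structure to exercise
stitching, split-read classification and coordinate accuracy, with every
knob explicit.

Per molecule:

1. With probability `junction_fraction` (default 0.8) the molecule is
   chimeric. Locus A is uniform over the genome (chromosomes weighted by
   length); with probability `trans_fraction` (default 0.1) locus B falls
   on a different chromosome (uniform choice), otherwise at a cis distance
   drawn from a density ∝ d^(−`cis_decay_exponent`) (default exponent 1,
   i.e. log-uniform) truncated to `cis_distance_range`
   (default 1 kb – 10 Mb). In `restriction` mode both loci snap to the
   nearest cut site (ties toward the lower coordinate); cut sites are the
   forward-strand occurrences of the motif (default `GATC`, MboI — its own
   reverse complement) plus virtual terminal cuts at 1 and L+1. In `mnase`
   mode (Micro-C) any position is a legal breakpoint and no snapping occurs.
2. Insert length ℓ ~ Normal(`insert_mean`=300, `insert_sd`=50), truncated to
   [2·20, 2·`read_length`+400] bp. The junction splits ℓ uniformly with a
   20 bp minimum arm, so junctions land at variable read cycles — this is
   what makes split-read classification non-trivial. Each arm is oriented
   at random: the A arm runs *into* cut A, the B arm runs *out of* cut B
   (reverse-complemented as needed), so the junction sits exactly between
   them.
3. Non-chimeric molecules are plain fragments of length ℓ anchored at a
   random cut site (uniform start in `mnase` mode); the truth record holds
   the two fragment ends.
4. Reads are the first `read_length` (150) bases from each end of the
   insert, read 2 reverse-complemented, with independent per-base
   substitution errors at `error_rate` (default 0.001) and a constant base
   quality (Q30). With probability `duplicate_fraction` the finished pair
   is re-emitted under a new read id as a PCR duplicate (same truth loci).

Coordinates are 1-based inclusive throughout (SAM/pairs convention). Truth
is per read id: one TSV row per emitted pair, duplicates sharing loci under
distinct ids. One boundary case: a locus snapped to the virtual terminal
cut of a chromosome is recorded as L+1.

What the simulator does *not* model: spurious (random religation) contacts,
whole-genome background reads, empirical insert-size distributions, indels,
quality degradation along the read, optical duplicates, and multi-way
(>2-locus) concatemers. Passing tests therefore demonstrate correctness of
the pipeline's bookkeeping and coordinate arithmetic on near-uniquely
mappable sequence — not robustness to repeats, SNPs or real error profiles.

## Preprocessing

Stage order is fixed: trim → dedup → stitch.

* **Trimming.** The adapter (Illumina TruSeq pair by default) is located as
  the longest suffix-anchored match of the adapter prefix, allowing one
  mismatch per 8 matched bases; matches shorter than 3 bp are ignored and a
  3 bp match at the extreme 3′ end must be exact. After adapter removal, 3′
  cycles below Q20 are trimmed. Mates are trimmed independently and keep
  their own lengths; a pair is dropped when either mate falls below 36 bp.
* **Deduplication.** Key = (first 16 bp of read 1, first 16 bp of read 2)
  as a tuple of post-trim sequences, so short reads of different lengths
  never collide. First occurrence wins. Multiple input FASTQ pairs
  (biological replicates) are concatenated *before* this stage.
* **Stitching.** Candidate overlaps o from min(len1, len2) down to 10 bp
  compare the read-1 suffix with the reverse-complemented read-2 prefix;
  the candidate minimizing mismatch fraction wins (ties to the larger
  overlap) and is accepted when the fraction ≤ 0.1. The threshold is
  deliberately stricter than permissive overlap mergers (0.25 is common):
  at 150 bp cycles a 10 % mismatch budget already tolerates realistic error
  rates while suppressing false merges between unrelated reads. Overlap
  bases take the higher-quality call (ties to read 1), quality = max.
  The overlap search is exhaustive — correctness over speed at the scales
  this package targets; the inner comparison is vectorized.
* **Auto mode.** The first 10 000 post-dedup pairs are probed; stitching is
  enabled when strictly more than 10 % of them stitch. An empty probe
  disables stitching.

## Aligner contract and invocation

Split reads must appear as supplementary (0x800) records, not secondary
(0x100); mates must be aligned independently (no mate rescue, no pairing
score); output must be name-grouped. The default templates run BWA-MEM with
`-S -P -5` (paired input) and `-5` (stitched single-end input), plus
`-k 13 -T 15`. The lowered seed length and score threshold let ligation
arms as short as the simulator's 20 bp minimum be reported as split
segments — on repeat-free test genomes such hits are still essentially
unique, and without them every short-arm chimera would collapse into a
one-segment alignment with a wrong "non-chimeric" pair. STAR-style output
is accepted by remapping MAPQ 255 (its "unique" code) to 60 before the
MAPQ ≥ 10 filter.

## Classification and extraction

After the MAPQ < 10 cut, records of one read whose query intervals overlap
reciprocally by > 50 % are collapsed to one region (highest MAPQ wins):
they re-describe the same stretch of the read, not a second locus.

Segment-count whitelist: stitched reads with 1 region (non-chimeric) or 2
regions (one junction); unstitched pairs with 1+1 regions, or 2+1 where one
split segment and the lone mate are two ends of the same fragment — same
chromosome, opposite strands, face-to-face, outermost-to-outermost span
≤ 1000 bp (`mate_join_max_span`; larger than any stitchable insert, smaller
than genuine long-range contacts). If both split segments qualify — only
possible for very short cis contacts — the smaller span wins. Everything
else (multi-way contacts included) is rejected with a reason that feeds the
run log, so groups in = pairs out + rejections. Reads with > 50 % of cycles
outside the union of their kept query intervals are rejected as overclipped
(union, not sum, so overlapping split alignments are not double-counted).

"Outermost end" is formalized as the mapped coordinate of the query base
most distal from the ligation junction, per locus: the query-start side for
mates' 5′ ends and for the first (by query) split segment, the query-end
side for the second. A locus's strand points from its outer base into the
fragment (`+` when the outer base sits at the segment's reference start).
This reproduces fragment-end reporting for non-chimeric reads,
(ref_start, +)/(ref_end, −), and conventional 5′-end reporting for 1+1
pairs. In the 2+1 case the reported loci are the *unpaired* split segment
(its junction-distal end) and the lone mate's 5′ end. Ends are swapped into
upper-triangle order (chromosome rank from the chrom-sizes file order, then
position); strands travel with their ends. Short cis pairs (< 1 kb) are
reported by default; a `min_span` filter exists but is off.

## Pairs output

4DN pairs v1.0: version line, `#sorted:` tag, one `#chromsize:` per
chromosome in order, `#columns:` declaration. Body sorted by
chr1-chr2-pos1-pos2 via an external merge over bounded-size runs (default
500 000 rows per run), so memory is flat in input size and the output is
byte-identical to a full in-memory sort. An eighth `category` column
records each pair's classification; readers ignore unknown extra columns
and accept space-separated dialects. Gzip output pins mtime and omits the
filename so identical runs are byte-identical.

## Evaluation

* **Accuracy vs truth** (tolerance 500 bp, strict `<`): a reported pair is
  correct when, under either end assignment, both chromosomes match and
  both distances are within tolerance. Pairs whose read id is missing from
  the truth table are binned as `unmatched` and excluded from the accuracy
  denominator (they cannot be scored either way). `recall_like` = truth
  records with a correct reported pair / all truth records; non-chimeric
  truths count when their fragment-end pair is recovered within tolerance.
* **Concordance** (tolerance 200 bp, strict `<`): join two runs on read id
  (first occurrence per file), consistent under the same both-ends rule;
  exclusive ids are counted both ways. The looser tolerance absorbs
  aligner-specific clipping of reported endpoints.
* **Stitch yield**: per stitched/unstitched class, reads in vs pairs out,
  plus the overall stitchable fraction.

All report fractions are printed alongside their integer numerators and
denominators.

## Problem sizes and numerical choices

The package's own validation runs at desk scale: a 3 Mb three-chromosome
uniform-random genome and 50 000 simulated read pairs for the end-to-end
accuracy and stitch-yield checks (a few minutes on one CPU), 10 000-draw
statistical checks against binomial/normal expectations (3 standard-error
bands), and exhaustive small-configuration enumeration (thousands of read
groups) against an independently written brute-force classifier. Thresholds
quoted above (MAPQ 10, 50 % clip, 10 % probe, 500/200 bp) are strict or
non-strict exactly as stated; boundary tests pin each one. All randomness
flows from explicit integer seeds; two runs with the same seed produce
byte-identical FASTQ, pairs and reports.

## Known limitations

* Alignment quality bounds everything: on repetitive genomes MAPQ
  filtering, not this package, decides which contacts survive.
* Multi-way concatemers are rejected rather than decomposed into pairwise
  contacts.
* The duplicate filter is sequence-prefix based; it cannot see duplicates
  that differ within the first 16 bp by sequencing error, nor
  alignment-level duplicates from different library molecules.
* The simulator's uniform junction placement and analytic insert
  distribution are idealizations; fractions derived from them (e.g. the
  stitchable share) describe the model, not any particular real library.
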