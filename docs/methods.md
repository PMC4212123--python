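# Methods

This document records the computational model, the parameter values and
why they were chosen, what the synthetic data generator does and does
not emulate, the numerical choices, and the known limitations.

## Pipeline model

The pipeline is a fixed-order funnel; every stage is a pure function of
its inputs and the seed, so partial runs are prefixes of the full run
and reruns are byte-identical.

### Read processing

Raw reads are 3'-adaptor products: the insert is everything preceding
the leftmost exact match of the first 8 nt of the adaptor
(`TGGAATTCTCGGGTGCCAAGG` by default).  An 8-nt seed tolerates
sequencing error in the distal adaptor while keeping trimming exact and
deterministic.  Reads without a seed match, shorter than 18 nt or longer
than 25 nt, or containing N, are discarded; reads matching an annotated
rRNA/tRNA sequence as a perfect substring on either strand are removed.
Surviving reads are collapsed to distinct sequences with per-library
counts, ordered by descending total count then lexicographically — the
downstream greedy selection depends on this total order.

### Mapping and abundance filtering

Distinct sequences are mapped to the genome requiring perfect identity
on either strand (an 18-mer prefix index makes this linear in genome
size).  Sequences with more than 30 genomic loci are treated as
repeat-associated siRNAs and removed.  The expression gate keeps, per
library and per read length, the top `ceil(0.05 · N)` distinct
sequences by count, including every sequence tied at the cut count; a
read identical to a known mature passes unconditionally.  Tie inclusion
makes the gate a pure function of the counts, not of an arbitrary sort
order.

### Hairpin discovery

Each surviving locus is examined in a ±400-bp strand-oriented window
(clamped at chromosome ends).  The window is folded; the mature's
pairing partner (shifted to leave 2-nt 3' overhangs) defines the
miR:miR\* duplex.  Acceptance requires all of:

| criterion | threshold | rationale |
| --- | --- | --- |
| MFE | < −30 kcal/mol (strict) | excludes marginally stable folds |
| MFE density | > 0.15 kcal/mol/nt (strict) | normalizes stability by length |
| consecutive duplex mismatches | < 4 | Dicer-substrate geometry |
| duplex bulges | < 3 | same |
| total mismatches + bulges | < 8 | same |

Accepted windows are trimmed to the innermost base pair enclosing the
duplex (the stem base) plus a 15-nt margin, then re-folded and
re-checked.  Trimming to the innermost enclosing pair rather than the
outermost is deliberate: in a 821-nt window random flank pairing almost
always creates a spurious outermost "enclosing" pair spanning most of
the window, which would leave precursors untrimmed and hundreds of
nucleotides long; the innermost pair recovers the biological precursor
(typically 80–160 nt here).

### Defining smRNA and classification

Reads are scanned greedily by length 21, then 22, then 20 nt, by
descending count and lexicographic tie-break.  Each read whose loci are
not already claimed is tested at every locus; if a hairpin is accepted,
the read becomes the precursor's *defining smRNA* and the precursor
extent is registered so no later read re-claims it.  The *reported
mature* is the most abundant 20–22-nt read falling entirely within
either duplex arm (±2 nt): the defining read only anchors the hairpin
and may be the star strand when the star happens to be 21 nt and the
mature 22 nt.

All placed reads (20–24 nt, fully inside the precursor, same strand)
drive the per-library classification.  With M = counts fully inside the
miR:miR\* region (each arm ±2 nt), S = counts overlapping the star
side, and O = the remaining counts:

- library not passing the abundance gate for the defining read, or
  M = 0 → unclassified;
- O empty → class 1 if S > 0 else 3;
- ΣO > M → class 5;
- mean(O) ≤ M/10 → class 2 if S > 0 else 4;
- otherwise unclassified.

The global class is the minimum over libraries.  Classes 1–2 are bona
fide.  Class 3–5 precursors are retained only if (a) the read signature
is Dicer-consistent — ≥75% of placed counts align within ±3 nt of the
miR or star span or fall inside the loop, and ≥60% of miR bases are
paired — and (b) the mature is within 3 mismatches of a bona fide
mature (rescue).

A mature candidate's final status is `known_exact` (catalogue match),
`known_variant` (≤3 mismatches from the catalogue), `novel_accepted`
(≥20% of its genomic loci yield accepted hairpins and ≥1 precursor
passes the signature gate) or `rejected`.

Genomic context uses the annotation with precedence CDS > UTR > intron
(inside a gene span with no exon overlap) > antisense (opposite-strand
CDS/exon) > intergenic; one shared base pair counts as overlap.

### Families and conservation

Greedy centroid clustering processes matures by descending count
(lexicographic tie-break); a mature joins the first family whose
representative aligns at some ungapped offset with ≤3 mismatches *and*
identity ≥84.2% of the shorter sequence (both conditions at the same
offset).  The 84.2% threshold is 16/19 — the identity of a 19-nt
overlap carrying 3 mismatches.  Conservation scans each homolog genome
for Hamming-distance ≤3 occurrences on either strand (vectorized over
genome positions); a hit in any outgroup genome makes the mature
`widespread`, otherwise a clade hit makes it `clade_specific`, else
`species_specific`.

### Target prediction and degradome validation

The reverse complement of the miRNA is aligned to each transcript with
an affine-gap Smith–Waterman: match +5, G:U +2, mismatch −3, gap open
−9, gap extend −4, with all scores doubled at miRNA positions 2–8 (the
plant cleavage-determining region).  A perfect 21-mer therefore scores
14·5 + 7·10 = 140, the score floor.  Non-overlapping sites are reported
by re-running the alignment on the transcript segments flanking each
accepted site.  Sites are kept when penalty ≤ 2 (mismatch 1, bulge
opening 2, G:U 0.5), aligned length ≥ 18, score ≥ 140 and duplex
hybridization energy ≤ −20 kcal/mol.  Degradome tags are mapped by
their first 20 nt; the cleavage position is the transcript base paired
with miRNA position 10.  Categories follow the t-plot convention
(0 unique maximum, 1 tied maximum, 2 above the median, 3 at/below, 4
count ≤ 1) and the positional p-value is the fraction of transcript
positions with count ≥ the cleavage count; validation requires
p ≤ 0.05.

### Polymorphism profiling

Counted variants are SNPs and ≤2-bp indels.  Each precursor contributes
a partition: the hairpin interval plus six strand-oriented 500-bp
windows (up_1000/up_500/up_1 upstream, dn_1/dn_500/dn_1000 downstream),
clamped at chromosome ends; every counted variant lands in exactly one
bucket.  Mature-region SNPs are reported as 1-based offsets from the
miRNA 5' end with flags for positions 10/11 (the cleavage-guiding
positions) and bins 1–7 / 8–12 / 13–21.  Hairpin SNPs get a structural
context from the MFE structure: `loop` (unpaired in the terminal loop),
`bulge` (otherwise unpaired), `near_bulge_1_2nt` (paired within 2 nt of
an unpaired stem base), `stem`; paired positions inside the star span
are flagged as duplex-disrupting.  The conserved-vs-novel comparison
uses a two-sided label-permutation test on per-precursor group mean
rates (add-one smoothed, 10,000 permutations, seeded per region), which
replaces parametric count models with an assumption-free resampling
test at these sample sizes.

## Synthetic data: what it does and does not emulate

The generator plants, on a random-background genome (~5 Mb, 2
chromosomes, GC ≈ 0.33):

- 30 miRNA loci spanning all five class regimes, each with a verified
  hairpin (the construct is checked against the discovery module's own
  acceptance predicates before embedding), a mature of 20–22 nt
  (mostly 21), ~70% 5'-U starts, and a realized star length of
  20–24 nt so the star is observable by the 20–24-nt placement rule;
- per-class read populations (mature ≫ star ≫ background for class 1/2,
  heavy outside reads for class 5, etc.) drawn from negative-binomial
  library models across 4 libraries, plus end-wobble variants;
- 5 siRNA repeat loci (35 genomic copies each), 4 rRNA/tRNA loci with
  abundant fragments, and length-stratified random background reads;
- a known-mature catalogue with exact entries, ≤3-mismatch variants and
  decoys; homolog genomes for clade/outgroup conservation with planted
  degenerate copies;
- a transcriptome with planted cleavable target sites (edits ≤ 2),
  penalty-3 decoy sites, and a degradome with concentrated tags at
  planted cleavage positions over uniform background;
- a variant panel with region-dependent SNP/indel rates (flank >
  hairpin > mature).

The embedding is checked so each planted window contains its mature
exactly once and no antisense copy, keeping the truth ledger an exact
scoring key.  The generator does **not** emulate: sequencing error
inside the insert (only end-wobble), quality scores, multi-mapping
ambiguity between miRNA families, splice isoforms, transposon
annotation, expression correlation structure between libraries, linkage
between variants, or genome assembly artifacts.  Absolute funnel counts
are therefore not comparable to real libraries; the planted-truth
*recoveries* are the meaningful quantities.

## Numerical choices

- **Folding**: a bundled nearest-neighbor dynamic program (stacking,
  hairpin, bulge and internal-loop tables; no multiloop penalty
  refinement, no dangles), Numba-accelerated, with an optional ViennaRNA
  backend for cross-checking.  On clean stem-loops the bundled engine
  agrees with ViennaRNA within ~25%; all thresholds are applied to the
  bundled engine's values, so results are self-consistent.
- **Smith–Waterman**: NumPy-vectorized row fill; the transcript-gap
  state uses a cumulative-maximum identity so each row stays O(n).
  Traceback uses a 1e-9 float tolerance.
- **Permutation test**: add-one smoothing ((hits+1)/(N+1)) keeps
  p-values strictly positive and unbiased under the null; the seed is
  offset per region so region tests are independent but reproducible.
- **Determinism**: every stochastic step draws from
  `numpy.random.default_rng(seed)` descendants; no wall-clock, hash or
  thread-order dependence reaches any output table.

## Limitations

- The 5-class scheme depends on the defining-smRNA registration order;
  a pathological tie structure could anchor a suboptimal precursor
  (mitigated by the deterministic count/lexicographic order).
- Perfect-match mapping misses matures carrying SNPs relative to the
  reference; the paper-scale remedy (mapping per accession) is out of
  scope.
- The bundled folding engine is simpler than ViennaRNA; borderline
  hairpins (MFE near −30) can be judged differently by the two engines.
- Conservation is a Hamming scan, not an alignment; homologs with
  indels inside the mature are missed.
- The degradome p-value is positional within one transcript and is not
  multiple-testing corrected across sites.
- The permutation comparison tests group mean rates only; it does not
  model per-precursor exposure differences beyond the rate
  normalization.
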