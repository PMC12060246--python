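# Methods

This note documents the models, parameter choices and numerical
conventions behind `asmqc`, and what the synthetic-data generator does and
does not emulate.

## Per-contig statistics

**GC content** is (G+C)/(A+C+G+T), case-insensitive; ambiguity codes are
excluded from numerator and denominator, and a sequence with no
unambiguous base returns NaN rather than a value.

**Unique k-mer fraction** is computed over *distinct* canonical k-mers:
the number of distinct canonical 21-mers seen exactly once divided by the
number of distinct canonical 21-mers. Canonicalisation (lexicographic
minimum of a k-mer and its reverse complement under the 2-bit encoding)
reflects double-stranded genomes and matches common k-mer counters;
`canonical=False` switches to strand-specific counting, and the
per-position alternative can be derived from the same counts. k = 21 is
the default (long enough to be near-unique in a mammalian genome, short
enough to be robust); k ≤ 32 is supported by the 64-bit packing.

**Depth** is the median per-base depth over a contig's full length
(uncovered bases count as zero) from primary, non-supplementary
alignments, at two strata: all reads, and reads with MAPQ strictly
greater than 20. Strict inequality is deliberate; the two strata are the
signal that separates collapsed repeats (high all-read, near-zero HQ
depth) from everything else. The median of an even count is the mean of
the central pair — depths are integers, so halves occur.

**Telomere enrichment** counts non-overlapping occurrences of TTAGGG and
its reverse complement (TTAGGG cannot overlap itself, so non-overlapping
equals sliding-window counting for the default motif) and divides the
per-bp density by a baseline. The baseline is the motif density over the
whole assembly, both strands — a whole-assembly rather than
nonrepetitive-only baseline, because the flag is meant to be computable
before any classification exists. Enrichment of a motif-free contig
against a zero baseline is 0; hits against a zero baseline report
infinity.

**Masked fraction** counts N/n plus lowercase acgt, so hard- and
soft-masked inputs both work.

**Contiguity.** N50 is the length at which the cumulative
sorted-descending length first reaches half the assembly; NG50 substitutes
half of an assumed genome size and is undefined (None) when the assembly
is shorter than that; L50 is the rank of the N50 contig.

## Contig classification

Depth cutoffs are *relative* to the estimated primary depth mode rather
than absolute, so the same rules work at any coverage; the defaults
(30/52 and 45/52 of the primary mode) reproduce absolute cutoffs of 30
and 45 when the primary mode is 52. Mode estimation builds a
length-weighted histogram at bin width 1, smooths with a centred moving
average (window 5, histogram padded past its maximum so an edge spike
still smooths into a symmetric plateau whose centre is the mode), and
takes the two highest local maxima at least 10 bins apart; a candidate
second mode must be separated from the primary by a genuine valley (the
minimum between them at most half the candidate's height), otherwise the
distribution is called unimodal. The primary mode is the higher-depth
peak of the top pair.

Rule precedence is collapsed-repeat before the depth rules, because
low-complexity contigs have unreliable high-MAPQ depth: their HQ-depth
values would otherwise satisfy the sex-candidate rule. A contaminant
assignment from the two-reference screen overrides everything. The
telomere flag (enrichment ≥ 4-fold) is set independently of the label.

## MinHash screen

Sketches keep the `sketch_size` smallest distinct SplitMix64 hashes of
the canonical k-mers; SplitMix64 is a fixed, documented constant mixer,
so sketches are reproducible across runs and platforms. Jaccard is
estimated with the bottom-sketch (merged-sketch) estimator, and the Mash
distance is d = −(1/k)·ln(2j/(1+j)), 0 at j = 1 and capped at 1 when
j = 0. A contig is flagged when its distance to the contaminant reference
is smaller than to the conspecific reference. Contigs below
`small_contig_bp` (default 10,000 bp — sketches of very short contigs are
noisy; the cutoff is a documented judgement call), or sharing no hashes
with either reference, fall back to comparing the single longest aligned
block per reference in a PAF (PAF column 11; a summed-blocks alternative
is available by flag). Ties and missing alignments stay unresolved
rather than guessing.

## Variant consensus

Normalization is the standard parsimony/left-alignment loop against the
assembly: shared terminal bases are dropped (extending left with the
reference base when an allele would empty), then shared leading bases are
dropped; output order is (contig, pos, ref, alt). The loop cannot shift
past position 1. Intersection requires normalized (sorted) input and
matches records exactly on (contig, pos, ref, alt); insertion vs deletion
designation is relative to the haploid assembly, which is arbitrary for a
diploid individual and is treated as such throughout.

Quality-dip detection smooths the integer-bin histogram with a window of
3, takes the two largest local maxima at least 5 bins apart whose
in-between minimum dips below half the smaller peak, and returns the
leftmost minimal bin strictly between them; histograms judged unimodal
return a configurable fallback (14 and 20 for the two callers in the
CLI). The smoothing window, separation and prominence rule are
implementation choices for an operation that is often done by eye; all
are parameters. Filtering keeps calls with quality strictly above the
threshold.

For annotation partitioning, a variant's anchor is its first altered base
— the position itself for SNVs, position + 1 for normalized indels (which
retain a shared anchor base). Exon takes precedence over intron for
overlapping features; interval membership is closed (boundary bases are
inside). Depletion fold is (genome exonic fraction)/(variant exonic
fraction), reported to one decimal. Density by contig class counts
heterozygous SNVs per kbp by default (a flag admits homozygous records),
aggregated as total SNVs over total class bp.

## Phasing summary

Blocks per contig are distinct PS values among phased heterozygous
records. Contigs whose heterozygous records are all unphased are reported
(with zero blocks) but excluded from the single-block and ≤3-block
fractions by default; the denominator policy (contigs with ≥ 1 phased
record, or all contigs) is recorded in the output because published
phasing fractions rarely state it. Haplotype-switch errors inside blocks
are not assessable from PS tags and are not modelled.

## BUSCO comparison

Category percentages use the four-category sum as denominator, to two
decimals; means round half away from zero to the nearest integer (banker's
rounding would mis-reproduce e.g. a 115.7 → 116 mean). Cross-species
means include the focal species by default, with a flag to exclude it.
Upset analysis is an exact set partition of BUSCO ids by presence pattern,
so cardinalities sum to the universe; ties are broken by pattern
bit-order in species order. The ancestral-loss adjustment subtracts the
count of BUSCOs missing in every species from each species' missing count
and from the lineage total; it refuses an adjustment larger than any
species' missing count. A BUSCO's status per species is categorical —
duplicated BUSCOs count once in upset universes.

## Synthetic data

The generator reproduces the structure the diagnostics consume, not
sequencing physics:

* **Contig classes.** Defaults: 10 autosomal contigs of 250–450 kbp at
  52×, 4 sex-linked of 150–350 kbp at 26×, 4 collapsed of 30–80 kbp, 2
  contaminant of 30–60 kbp — about 5 Mbp over 20 contigs, a scale at
  which every stage runs in seconds while per-contig depth and rate
  estimates are stable. GC is 0.41 for host classes and 0.58 for the
  contaminant composition model, which also uses an independent random
  k-mer source.
* **Collapsed contigs** are a 50-bp seed unit tiled to length plus a
  3-kbp telomere array (TTAGGG). They are pure tandem arrays by default:
  a point-mutation load as small as 0.1 % would add thousands of unique
  21-mers against a ~60-k-mer distinct-k-mer denominator and erase the
  low-uniqueness signal the class must carry. All-read target depth is
  150× (collapsed copies attract reads from every copy); reads from these
  contigs get MAPQ 0 with probability 0.95 (ambiguous-placement proxy),
  all other reads MAPQ 60.
* **Reads** are error-free, ungapped, uniform-start tilings at the target
  depth (count = depth·L/read length, default 1 kbp reads), which keeps
  the pileup oracle exact. No base errors, no read-length distribution,
  no structural variation.
* **Annotation**: non-overlapping gene models at 9 genes/Mbp with 2–8
  exons, exponential exon/intron lengths around means of 156 and 1,605 bp
  — mammalian-like values yielding a genome that is roughly 0.7 % exonic
  and 6 % intronic.
* **Call sets.** True heterozygous variants are planted at 2.4 SNVs/kbp
  and 0.2 indels/kbp on autosomes, 0.11 SNVs/kbp on sex contigs, zero on
  collapsed/contaminant contigs. Exonic indels are thinned 3.5-fold, and
  frame-disrupting exonic indels a further 5-fold. Every true variant
  appears in both call sets; caller-specific false SNVs are added at 0.5
  per kbp of assembly on positions disjoint from the truth and from each
  other (disjointness makes the call-set intersection exactly the truth —
  the false-call model is SNV-only for the same reason, since two
  independent indel errors in one homopolymer could normalize to the same
  key). Qualities are integer-rounded normal draws clamped to 1–60:
  error mode N(8,2) vs true mode N(30,6) for caller A and N(13,3) vs
  N(34,6) for caller B, calibrated so the analytic valley of the expected
  smoothed histogram sits at quality 14 and 20 respectively; the planted
  valley recorded in the truth is recomputed from the realized error/true
  ratio of each run.
* **Phase blocks.** Per contig with true variants, a planted block count
  is drawn from {1,…,5} with probabilities (0.55, 0.15, 0.10, 0.10,
  0.10) — matching a phasing profile where 55 % of contigs form a single
  block and 80 % at most three — and caller A's true calls are split into
  that many contiguous PS groups. False calls stay unphased.
* **BUSCO fixtures** plant an all-species-missing block (default 33), a
  configurable set of lineage-specific single-copy patterns, and
  single-copy-everywhere for the remainder, over a 12,234-BUSCO universe
  across 10 species.

All randomness flows through one seeded generator per operation;
identical spec + seed gives byte-identical FASTA/SAM/VCF/GFF3/TSV output.

What passing tests on this generator shows: the statistics, thresholding
rules, set operations and truth-recovery logic are correct on data with
exactly the planted structure. What it does not show: robustness to base
errors, mapping artefacts, annotation noise, caller-specific biases or
repeat families in real assemblies.

## Degenerate inputs and numerical conventions

Empty sequences, empty length lists, all-zero depth vectors, zero
category totals and unphased inputs raise `ValueError` with the offending
field named. Fractions that would divide by zero return NaN (GC of an
all-N sequence, unique-k-mer fraction with no valid window) or an
explicit infinity flag (telomere enrichment over a zero baseline).
Variant collisions during simulation are dropped (later draw loses) and
logged. The pipeline's per-stage manifests record parameters and input
checksums, so reruns reuse unchanged stage outputs and a rerun without
changes is byte-identical.

## Known limitations

* The collapsed-contig model is a single tandem family per contig; real
  collapsed regions mix families and carry divergence.
* The contaminant screen assumes exactly two candidate references.
* Genotype-level analyses are limited to het/hom parsing of GT strings;
  there is no genotype-likelihood model.
* The dip detector assumes a two-mode quality mixture; more complex
  mixtures fall back to the configured threshold.
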