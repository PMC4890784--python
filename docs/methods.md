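# Methods

## The analysis in one paragraph

`vsrna` models and analyses the small-RNA response of a filamentous fungus
to a resident non-segmented dsRNA mycovirus. Multiplexed small-RNA reads
are demultiplexed by inline barcode and stripped of their 3' adapter;
cleaned inserts (18–30 nt, no N) are aligned to an expanded reference
(host contigs plus the viral genome) allowing **perfect matches only** and
reporting **all** placements on both strands; each mapped read receives a
single genomic category; viral reads are profiled by strand, size, 5'
nucleotide, and per-nucleotide position; scaled abundances are compared
across genotypes with one-way ANOVA and Tukey HSD; and the virus itself is
recovered de novo from RNA-seq reads that fail to map to the host-only
reference, then structurally annotated (ORFs, frames, UTRs, inter-ORF
spacer, −1 frameshift slippery-site candidates).

## Coordinates, scaling, counting rules

* Coordinates are 0-based half-open in memory, 1-based inclusive in every
  file and report (an ORF "17–991" includes both endpoints and its stop
  codon).
* RPM = count / library total × 10⁶. The default denominator is the number
  of reads *assigned by the parser* ("per million of total reads");
  `RunConfig.rpm_denominator="mapped"` switches to mapped-read scaling.
* Category tallies and per-feature totals are **read-level** — a
  multi-mapping read counts once, so category percentages sum to 100.
  Per-nucleotide densities are **hit-level** — every placement of a
  multi-mapper contributes — which preserves the all-hits alignment
  contract where it matters (positional coverage).
* A read with viral hits on both strands is assigned the majority strand;
  ties resolve to sense and are counted in a tie log.
* Sense is the viral strand encoding the ORFs.
* Ratios with zero denominators (sense:antisense with no antisense reads,
  sRNA:RNA-seq with no viral RNA-seq) are reported as undefined, never as
  infinity.
* sRNA:RNA-seq ratios divide each small-RNA replicate's viral RPM by the
  **genotype-mean** viral RNA-seq RPM; per-nucleotide density
  normalisation likewise uses the genotype's strand-specific mean.

## Demultiplexing

A raw read is `insert + adapter + barcode + filler` (the
barcode-before-adapter layout is a config switch; the adapter constant
region defaults to `CTGTAG`). Matching is exact at the leftmost adapter
occurrence; barcodes are fixed-length and prefix-free. Every read receives
exactly one fate — `assigned`, `no_adapter`, `unknown_barcode`,
`contains_N`, or `too_short` (which also absorbs inserts above the 30-nt
ceiling; the fate set is closed and the log asserts that fates partition
the input). Failure precedence: no adapter → unknown barcode → N →
length.

## Exact-match alignment

A seed k-mer index (k = 12 by default, below the 18-nt insert minimum)
with full-length verification; k-mers containing N are never indexed, so
nothing aligns across ambiguity. Hits are ordered (contig, start, + before
−) for determinism. A brute-force `str.find` scan over both strands
(`naive_scan`) is kept as the independent oracle; the test suite asserts
exact hit-set equality over hundreds of random cases. This aligner is
deliberately desk-scale: exactness, not throughput, is the contract, and
it is not intended to replace a production short-read aligner on
genome-scale data.

## Group statistics

One-way fixed-effects ANOVA by explicit sums of squares; Tukey HSD with
the Tukey–Kramer standard error under imbalance,
SE = sqrt(MS_within/2 · (1/nᵢ + 1/nⱼ)), and the critical value from the
studentized-range distribution (scipy's implementation; numerical
tolerance far below the unit precision at which intervals are reported).
An interval excluding zero coincides with adjusted p < α. All data
identical gives a flagged degenerate result. Significance letters can be
referenced to a control group (the "a" annotation style) or computed as
compact letter classes. A vectorised Monte-Carlo routine measures the
family-wise type-I error of exactly this procedure (same statistic, same
critical value — asserted in the tests) under the global null.

## Virus discovery

Unmapped reads are exactly those with empty hit lists against the
host-only reference. Assembly is a greedy exact suffix–prefix merger:
repeatedly join the pair with the longest overlap ≥ `min_overlap` (both
orientations; ties broken lexicographically for determinism; containment
absorbs). For error-free reads tiling a non-repetitive template this
reconstructs the template exactly or as its reverse complement; it is a
deliberately simple assembler for desk-scale, error-free input, with a
hook to import externally assembled contigs instead, and contigs matching
a user-supplied decoy set (e.g. rRNA/mitochondrial sequence) are excluded
before ranking. For the RNA-seq discovery stage assembly takes the most
abundant distinct unmapped sequences (up to 1,500) — high-coverage
transcripts are the assembly target, and abundance ranking keeps singleton
background reads from crowding them out of the quota — while ranking
assigns **all** unmapped reads to the first
(longest-first) contig containing them verbatim in either orientation —
so the reported "fraction of unmapped reads" uses exact containment, a
declared simplification relative to re-aligning reads against contigs.

ORF finding reports maximal ATG→stop ORFs (first ATG per stop-bounded
stretch, end includes the stop, so 975 nt ↔ 324 aa), with frame
((start−1) mod 3)+1. Layout arithmetic: 5' UTR = orf1.start − 1, spacer =
orf2.start − orf1.end − 1 (negative ⇒ overlap flag), 3' UTR = genome
length − last ORF end. The principal ORFs of a contig are selected
longest-first without overlap; a contig is oriented to the strand carrying
the longest ORF before annotation. Slippery-heptamer scanning covers a
21-nt window ending at the last codon before the first ORF's stop; the
default detection rule (final four bases identical and A/U) is a declared
heuristic chosen to detect homopolymer-tailed heptamers such as
`G GAU UUU`; the canonical `X XXY YYZ` rule is available as an
alternative.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed once:

* Reference: three host contigs (12/10/8 kb) of uniform random sequence
  carrying non-overlapping features (structural RNA, mitochondrial, TE,
  repeat, protein-coding) and a 2,923-nt virus with ORF1 at 17–991
  (frame 2) and ORF2 at 1081–2817 (frame 1), a `GGATTTT` heptamer whose
  last base abuts the ORF1 stop, no internal or upstream-extending in-frame
  starts, and no adapter sequence on either strand (which would corrupt
  parsing).
* Eight genotypes, mirroring a silencing-mutant panel: five
  control-like strains (sense fraction 0.597 → sense:antisense 1.48; 5'U
  0.75; 21-nt-peaked sizes; viral sRNA fraction 0.04666 against viral
  RNA-seq fraction 0.002 → sRNA:RNA-seq ≈ 23.3), two DCL-loss strains
  whose "viral" small RNAs are heavily contaminated with plus-strand
  degradation fragments (uniform start, uniform 18–30 length, unbiased 5'
  nt — observed ratios ≈ 3.7 and ≈ 9.5, 5'U ≈ 25%, broad ≥23-nt-shifted
  sizes, sRNA:RNA-seq ≈ 0.28 and ≈ 0.06), and an AGO-loss strain that
  over-accumulates viral siRNA while viral RNA rises (5'U ≈ 45%,
  sRNA:RNA-seq ≈ 0.9). A ninth, AGO2-like strain is omitted from the
  default panel as statistically indistinguishable from control; it can be
  added via config. An IP design (`ip_experiment_genotypes`) models an
  AGO pulldown retaining 5'U reads at 99%.
* A read's 5' nucleotide is realised by conditioning its start position on
  the first base, so every emitted read is a verbatim genome substring
  (perfect-match alignable) while the 5'-nt law is exact. Hotspots are a
  per-nucleotide categorical weight vector (uniform by default) — real
  hotspots exist but no generative law for them is claimed.
* Decoy reads (random sequence verified absent from the reference) model
  unalignable material; the DCL-loss RNA-seq decoy fraction is set so the
  dominant non-genomic contig absorbs ≈ 79% of unmapped reads.
* One top-level seed; each library draws from a child stream keyed on
  (seed, sample name), so adding a sample never perturbs the others.
  Constant quality strings (the parser is sequence-only). No sequencing
  errors, no paired ends, no PCR duplicates — so passing tests demonstrate
  the correctness of the computations under the declared generative laws,
  not robustness to base-calling noise or adapter mismatches that real
  libraries contain.

Because the configured PMFs describe *true* siRNAs, recovery tests compare
pipeline output against `expected_observed_profile`, the closed-form
mixture of the configured law with the degradation-fragment law.

## Problem sizes

Unit tests run a 2-genotype × 2-replicate experiment at 4,000 reads per
library; the end-to-end acceptance test runs the full 8 × 4 × 10⁵ design;
the analysis drivers use 8 genotypes × 2 replicates at 20,000 reads per
library; the acceptance script uses 8 genotypes × 3 replicates at 50,000
small-RNA and 60,000 RNA-seq reads per library (the RNA-seq depth sets the
precision of the genotype-mean ratio denominators), and 10⁴ null
replicates for the Tukey
family-wise error measurement. These sizes were chosen so every statistic
they support is estimated to well within its comparison tolerance.

## Known limitations

* The aligner and assembler are exact-match tools; any sequencing error
  makes a read unmappable/unmergeable by design.
* Greedy assembly can split a template when read starts leave coverage
  gaps larger than (read length − min_overlap); the discovery driver's
  subsample size keeps this probability negligible at default settings.
* Category precedence for multi-category reads (viral > structural RNA >
  mitochondrial > TE > repeat > protein-coding) is a declared convention,
  config-overridable; other orderings change Fig-style category tables but
  nothing else.
* The Pearson correlation for IP/input comparisons is computed on raw
  unique-sequence counts by default (log1p optional); heavy-tailed count
  distributions make the raw-scale value sensitive to the most abundant
  sequences.
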