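# vsrna — viral small-RNA profiling of a dsRNA mycovirus in a fungal host

Filamentous fungi silence resident viruses with the quelling machinery:
Dicer-like (DCL) enzymes dice viral dsRNA into 18–30-nt small interfering
RNAs, and an Argonaute (AGO) loads the ones it prefers (21 nt, 5' U) to
target viral RNA. `vsrna` is the complete computational side of such a
study for a non-segmented dsRNA mycovirus: it takes multiplexed small-RNA
and strand-specific RNA-seq libraries from a panel of silencing-mutant
genotypes and produces every statistic that characterises the antiviral
response, plus the discovery and structural annotation of the virus
itself. A synthetic-data module generates all inputs with the statistical
structure the analysis assumes, so the entire pipeline runs, and is
tested, with no external data.

It is written for bioinformaticians analysing fungal (or other compact)
small-RNA datasets who need exact, inspectable implementations of the
standard steps rather than a black-box workflow.

## What it computes

* **Demultiplexing / adapter trimming** — exact inline-barcode parsing
  with a five-fate accounting log that provably partitions the input
  (`assigned`, `no_adapter`, `unknown_barcode`, `contains_N`, `too_short`).
* **Perfect-match, all-hits alignment** — a seed-and-verify exact-match
  aligner reporting *every* placement of a read on both strands, with a
  brute-force oracle used in the tests.
* **Categorisation** — one category per read over all of its hits
  (viral > structural RNA > mitochondrial > TE > repeat > protein-coding >
  non-annotated), so category percentages sum to 100.
* **Viral siRNA statistics** — RPM = count/total × 10⁶; sense:antisense
  strand ratio; size × strand distributions (% of each strand's viral
  reads at 18–30 nt); 5'-nucleotide distributions; the per-replicate
  ratio sRNA-RPM / genotype-mean-RNA-seq-RPM; hit-level per-nucleotide
  densities, optionally normalised by strand-mean RNA-seq; AGO-IP vs
  input unique-sequence Pearson correlation and enrichment.
* **Group comparisons** — one-way ANOVA and Tukey HSD (Tukey–Kramer under
  imbalance) with family-wise 95% intervals and control-referenced
  significance letters.
* **Virus discovery** — unmapped-read triage, a deterministic greedy
  exact-overlap assembler, contig ranking by the fraction of unmapped
  reads absorbed, and genome-layout annotation: maximal ORFs with frame
  labels ((start−1) mod 3 + 1), UTRs, inter-ORF spacer, and −1 ribosomal
  frameshift slippery-heptamer candidates.

See `docs/methods.md` for the model, counting rules, and every numerical
convention.

## Worked example

Run the numbered drivers in order (each is a thin wrapper over the
library and writes its tables under `results/`):

```bash
cd analysis
python 01_simulate.py
python 02_preprocess.py
python 03_align_categorize.py
python 04_profile.py
python 05_group_stats.py
python 06_discover_virus.py
python 07_report.py
```

`04_profile.py` prints one row per library (abridged to three genotypes):

```
     sample  total_reads  viral_reads  viral_rpm  ratio_sense_antisense  pct_5pU  sr_to_rnaseq
 control_r1        20000          882  44100.000                  1.617   74.376        26.727
    dcl1_r1        20000         1120  56000.000                  3.891   25.179         0.284
    ago1_r1        20000         5573 278650.000                  1.494   44.177         0.889

control means: sense:antisense 1.51, 5'U 74.4%, sRNA:RNA-seq 28.09
```

Reading: in the silencing-proficient control, viral siRNAs come from both
strands without strong bias (ratio ≈ 1.5), three quarters start with U
(the AGO-preferred 5' nucleotide), and small-RNA output is tens of times
the viral RNA-seq signal — an active, efficient dicing response. In the
DCL-loss strain the "viral small RNAs" are dominated by plus-strand
degradation fragments (ratio ≈ 3.9, 5'U ≈ 25%), and in the AGO-loss
strain siRNA production continues but viral RNA accumulates, collapsing
the sRNA:RNA-seq ratio to ≈ 0.9. `05_group_stats.py` flags exactly the
DCL1- and AGO1-loss genotypes as differing from control.

`06_discover_virus.py` then recovers the virus from RNA-seq reads that
fail to map to the host-only reference:

```
9,936 unmapped RNA-seq reads -> 1 contigs
dominant contig: 2,921 nt, absorbs 79.5% of unmapped reads
layout: 5'UTR 16 nt | ORF1 17-991 (frame 2, 324 aa) | spacer 89 nt | ORF2 1081-2817 (frame 1, 578 aa) | 3'UTR 104 nt
slippery candidate GGAUUUU at 982 (0 nt from the ORF1 stop)
```

The two ORFs sit in different frames with a homopolymer-tailed heptamer
immediately upstream of the first stop codon — the signature of a −1
ribosomal frameshift producing a capsid–RdRP fusion. (At this sequencing
depth the assembled contig misses the last two bases of the 2,923-nt
genome, hence the 104-nt 3' UTR.)

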