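"""End-to-end orchestration: demultiplex -> align -> categorize -> profile ->
group statistics -> virus discovery -> report tables.

All heavy lifting happens in the per-stage modules; this layer aggregates
per-library statistics efficiently by working on *unique* insert sequences
(each distinct sequence is aligned and categorised once, then weighted by
its multiplicity) and exposes ``run_stage`` so the numbered analysis drivers
and the acceptance script stay thin.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import Hit, ReferenceIndex, align_unique, build_index
from .errors import ConfigurationError
from .features import FeatureSet, categorize_read, category_table
from .formats import RunConfig, read_fasta, read_sample_sheet, write_manifest, write_table
from .preprocess import ParseLog, demultiplex_run
from .profiling import (ViralProfile, five_prime_distribution, rpm,
                        size_strand_distribution, strand_ratio)
from .stats import TukeyResult, significance_letters, tukey_hsd
from .synthetic import VIRUS_CONTIG

# ---------------------------------------------------------------------------
# Small-RNA analysis


@dataclass
class SmallRnaAnalysis:
    """Per-sample outcome of the small-RNA arm of the pipeline."""

    parse_log: ParseLog
    profiles: dict[str, ViralProfile]
    category_counts: dict[str, Counter]
    mapped: dict[str, int]
    unmapped: dict[str, int]
    viral_unique: dict[str, Counter] = field(repr=False, default_factory=dict)
    strand_ties: dict[str, int] = field(default_factory=dict)

    def category_frame(self) -> pd.DataFrame:
        return category_table(self.category_counts)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.summary_row() for p in self.profiles.values()])


def analyze_small_rna(fastq, barcodes: dict[str, str], reference: dict[str, str],
                      features: FeatureSet, config: RunConfig | None = None,
                      virus_contig: str = VIRUS_CONTIG) -> SmallRnaAnalysis:
    """Demultiplex a multiplexed small-RNA FASTQ and compute every per-sample
    viral statistic against the expanded (virus-containing) reference.

    ``barcodes`` maps barcode -> sample.  The RPM denominator follows
    ``config.rpm_denominator``: parsed (assigned) reads by default, mapped
    reads as the alternative.
    """
    config = config or RunConfig()
    per_sample, log = demultiplex_run(
        fastq, barcodes, adapter_prefix=config.adapter,
        min_len=config.min_len, max_len=config.max_len,
        layout=config.barcode_layout)
    index = build_index(reference, k=config.k)
    virus_length = index.contig_lengths.get(virus_contig, 0)

    cache: dict[str, list[Hit]] = {}
    profiles: dict[str, ViralProfile] = {}
    categories: dict[str, Counter] = {}
    mapped: dict[str, int] = {}
    unmapped: dict[str, int] = {}
    viral_unique: dict[str, Counter] = {}
    ties: dict[str, int] = {}

    for sample in sorted(per_sample):
        inserts = per_sample[sample]
        hits_by_seq = align_unique(index, inserts, cache=cache)
        cat_counts: Counter = Counter()
        n_mapped = n_unmapped = 0
        sense = antisense = n_tie = 0
        size_sense: Counter = Counter()
        size_anti: Counter = Counter()
        first_bases: Counter = Counter()
        vu: Counter = Counter()
        dens_sense = np.zeros(virus_length)
        dens_anti = np.zeros(virus_length)
        for seq, mult in inserts.items():
            hits = hits_by_seq[seq]
            if not hits:
                n_unmapped += mult
                continue
            n_mapped += mult
            category = categorize_read(hits, features)
            cat_counts[category] += mult
            if category != "viral":
                continue
            vu[seq] += mult
            viral_hits = [h for h in hits if h.contig == virus_contig]
            plus = sum(1 for h in viral_hits if h.strand == "+")
            minus = len(viral_hits) - plus
            if plus == minus:
                n_tie += mult
            if plus >= minus:  # tie resolves to sense
                sense += mult
                size_sense[len(seq)] += mult
            else:
                antisense += mult
                size_anti[len(seq)] += mult
            first_bases[seq[0]] += mult
            for h in viral_hits:  # hit-level: every placement contributes
                if h.strand == "+":
                    dens_sense[h.start:h.end] += mult
                else:
                    dens_anti[h.start:h.end] += mult

        if config.rpm_denominator == "parsed":
            total = log.per_sample.get(sample, 0)
        elif config.rpm_denominator == "mapped":
            total = n_mapped
        else:
            raise ConfigurationError(
                f"rpm_denominator must be 'parsed' or 'mapped', got "
                f"{config.rpm_denominator!r}")
        size_df, _pooled = size_strand_distribution(size_sense, size_anti)
        profiles[sample] = ViralProfile(
            sample=sample, total_reads=total, viral_reads=sense + antisense,
            sense_reads=sense, antisense_reads=antisense,
            sense_rpm=rpm(sense, total) if total else 0.0,
            antisense_rpm=rpm(antisense, total) if total else 0.0,
            ratio_sense_antisense=strand_ratio(sense, antisense),
            size_by_strand=size_df,
            five_prime=(five_prime_distribution(first_bases) if first_bases else {}),
            per_nt_sense=dens_sense / total * 1e6 if total else dens_sense,
            per_nt_antisense=dens_anti / total * 1e6 if total else dens_anti,
        )
        categories[sample] = cat_counts
        mapped[sample], unmapped[sample] = n_mapped, n_unmapped
        viral_unique[sample] = vu
        ties[sample] = n_tie
    return SmallRnaAnalysis(parse_log=log, profiles=profiles,
                            category_counts=categories, mapped=mapped,
                            unmapped=unmapped, viral_unique=viral_unique,
                            strand_ties=ties)


# ---------------------------------------------------------------------------
# RNA-seq analysis


def analyze_rnaseq(fastq_paths: dict[str, Path], reference: dict[str, str],
                   config: RunConfig | None = None,
                   virus_contig: str = VIRUS_CONTIG) -> pd.DataFrame:
    """Align per-sample RNA-seq FASTQs and tally viral reads by strand.

    Returns one row per sample: totals, mapped/unmapped, viral sense and
    antisense counts, and their RPM values (per million reads in the
    library).
    """
    from .formats import iter_fastq

    config = config or RunConfig()
    index = build_index(reference, k=config.k)
    rows = []
    for sample in sorted(fastq_paths):
        counts: Counter = Counter()
        for _rid, seq, _q in iter_fastq(fastq_paths[sample]):
            counts[seq.upper()] += 1
        hits_by_seq = align_unique(index, counts)
        total = sum(counts.values())
        n_mapped = viral = v_sense = v_anti = 0
        for seq, mult in counts.items():
            hits = hits_by_seq[seq]
            if not hits:
                continue
            n_mapped += mult
            viral_hits = [h for h in hits if h.contig == virus_contig]
            if not viral_hits:
                continue
            viral += mult
            plus = sum(1 for h in viral_hits if h.strand == "+")
            if plus >= len(viral_hits) - plus:
                v_sense += mult
            else:
                v_anti += mult
        rows.append({
            "sample": sample, "total_reads": total, "mapped": n_mapped,
            "unmapped": total - n_mapped, "viral_reads": viral,
            "viral_sense": v_sense, "viral_antisense": v_anti,
            "viral_rpm": rpm(viral, total) if total else 0.0,
            "viral_sense_rpm": rpm(v_sense, total) if total else 0.0,
            "viral_antisense_rpm": rpm(v_anti, total) if total else 0.0,
        })
    return pd.DataFrame(rows)


def attach_rnaseq_normalization(analysis: SmallRnaAnalysis, rnaseq: pd.DataFrame,
                                sample_sheet: pd.DataFrame) -> None:
    """Fill each profile's sRNA:RNA-seq ratio using genotype-mean RNA-seq RPM.

    Each small-RNA replicate's viral RPM is divided by the *average* viral
    RNA-seq RPM of the replicate's genotype; genotypes without RNA-seq (or
    with zero viral RNA-seq) keep the undefined flag (None).
    """
    genotype_of = dict(zip(sample_sheet["sample"], sample_sheet["genotype"]))
    rnaseq = rnaseq.assign(genotype=rnaseq["sample"].map(genotype_of))
    means = rnaseq.groupby("genotype")["viral_rpm"].mean()
    for sample, profile in analysis.profiles.items():
        genotype = genotype_of.get(sample)
        mean_rpm = means.get(genotype, 0.0)
        profile.sr_to_rnaseq = (profile.viral_rpm / mean_rpm
                                if genotype is not None and mean_rpm > 0 else None)


def rnaseq_strand_means(rnaseq: pd.DataFrame, sample_sheet: pd.DataFrame,
                        ) -> pd.DataFrame:
    """Per-genotype mean viral RNA-seq RPM by strand (density normalizers)."""
    genotype_of = dict(zip(sample_sheet["sample"], sample_sheet["genotype"]))
    df = rnaseq.assign(genotype=rnaseq["sample"].map(genotype_of))
    return df.groupby("genotype")[["viral_sense_rpm", "viral_antisense_rpm"]].mean()


# ---------------------------------------------------------------------------
# Group statistics over genotypes


def genotype_groups(values_by_sample: dict[str, float],
                    sample_sheet: pd.DataFrame) -> dict[str, list[float]]:
    genotype_of = dict(zip(sample_sheet["sample"], sample_sheet["genotype"]))
    groups: dict[str, list[float]] = {}
    for sample, value in values_by_sample.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        groups.setdefault(genotype_of[sample], []).append(value)
    return groups


def compare_genotypes(values_by_sample: dict[str, float],
                      sample_sheet: pd.DataFrame, alpha: float = 0.05,
                      reference: str = "control") -> tuple[TukeyResult, dict[str, str]]:
    """One-way ANOVA + Tukey HSD across genotypes with control-referenced
    significance letters."""
    groups = genotype_groups(values_by_sample, sample_sheet)
    result = tukey_hsd(groups, alpha=alpha)
    letters = significance_letters(
        result, reference=reference if reference in groups else None)
    return result, letters


# ---------------------------------------------------------------------------
# Virus discovery


def discover_virus(reads: list[str], host_reference: dict[str, str],
                   config: RunConfig | None = None, assemble_limit: int = 1500,
                   decoy_contigs: dict[str, str] | None = None):
    """Recover the dominant non-genomic transcript from an RNA-seq read set.

    Aligns reads to the host-only reference, assembles the most abundant
    distinct unmapped sequences (up to ``assemble_limit``; high-coverage
    transcripts are exactly what assembly is after, and abundance ranking
    keeps unique background reads from crowding them out) with the greedy
    exact-overlap assembler, excludes contigs matching a user-supplied decoy
    set, and ranks contigs by the fraction of *all* unmapped reads they
    contain.  Returns ``(ranked contigs, unmapped reads)``.
    """
    from .align import align_library
    from .discovery import collect_unmapped, greedy_assemble, rank_contigs

    config = config or RunConfig()
    index = build_index(host_reference, k=config.k)
    alignment = align_library(index, reads)
    unmapped = collect_unmapped(alignment, reads)
    counts = Counter(unmapped)
    ordered = sorted(counts, key=lambda s: (-counts[s], s))
    unique = sorted(ordered[:assemble_limit])
    contigs = greedy_assemble(unique, min_overlap=config.min_overlap)
    if decoy_contigs:
        from .align import revcomp
        decoys = {s.upper() for s in decoy_contigs.values()}
        decoys |= {revcomp(s) for s in decoys}
        contigs = [c for c in contigs
                   if not any(c.sequence in d or d in c.sequence for d in decoys)]
    return rank_contigs(contigs, unmapped), unmapped


# ---------------------------------------------------------------------------
# Consolidated report


def report_tables(analysis: SmallRnaAnalysis, rnaseq: pd.DataFrame | None,
                  sample_sheet: pd.DataFrame, layout=None,
                  alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """All panel-equivalent tables: category percentages, viral RPM with
    significance letters, strand ratios, size/5'-nt distributions,
    sRNA:RNA-seq ratios, RNA-seq strand tables, and the virus layout."""
    genotype_of = dict(zip(sample_sheet["sample"], sample_sheet["genotype"]))
    tables: dict[str, pd.DataFrame] = {}
    tables["parse_log"] = analysis.parse_log.to_frame()
    tables["category_percentages"] = analysis.category_frame()

    summary = analysis.summary_frame()
    summary["genotype"] = summary["sample"].map(genotype_of)
    tables["viral_srna_summary"] = summary

    def letters_frame(metric: str) -> pd.DataFrame:
        values = {row["sample"]: row[metric] for _, row in summary.iterrows()}
        groups = genotype_groups(values, sample_sheet)
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            return pd.DataFrame(columns=["genotype", "mean", "letters"])
        result, letters = compare_genotypes(values, sample_sheet, alpha=alpha)
        rows = [{"genotype": g, "mean": float(np.mean(v)), "letters": letters.get(g, "")}
                for g, v in sorted(groups.items())]
        tables[f"tukey_{metric}"] = result.pairs
        return pd.DataFrame(rows)

    tables["viral_rpm_by_genotype"] = letters_frame("viral_rpm")
    if summary["sr_to_rnaseq"].notna().any():
        tables["sr_to_rnaseq_by_genotype"] = letters_frame("sr_to_rnaseq")

    size_rows, fp_rows = [], []
    for sample, profile in analysis.profiles.items():
        if profile.size_by_strand is not None:
            df = profile.size_by_strand.reset_index().assign(sample=sample)
            size_rows.append(df)
        for base, pct in profile.five_prime.items():
            fp_rows.append({"sample": sample, "base": base, "percent": pct})
    if size_rows:
        tables["size_by_strand"] = pd.concat(size_rows, ignore_index=True)
    if fp_rows:
        tables["five_prime"] = pd.DataFrame(fp_rows)

    if rnaseq is not None and not rnaseq.empty:
        tables["rnaseq_viral"] = rnaseq.assign(
            genotype=rnaseq["sample"].map(genotype_of))

    if layout is not None:
        orf_rows = [{"record": f"orf{i + 1}", "start": o.start, "end": o.end,
                     "frame": o.frame, "length_nt": o.length_nt,
                     "length_aa": o.length_aa} for i, o in enumerate(layout.orfs)]
        meta = [{"record": "genome", "start": 1, "end": layout.genome_length,
                 "frame": np.nan, "length_nt": layout.genome_length,
                 "length_aa": np.nan}]
        tables["virus_layout"] = pd.DataFrame(meta + orf_rows)
        tables["virus_layout_metrics"] = pd.DataFrame([{
            "five_prime_utr_nt": layout.five_prime_utr_nt,
            "three_prime_utr_nt": layout.three_prime_utr_nt,
            "spacer_nt": layout.spacer_nt,
            "frameshift_candidate": layout.frameshift_candidate,
            "slippery_sites": ";".join(
                f"{s.sequence}@{s.position}(d={s.distance_to_stop})"
                for s in layout.slippery_sites),
        }])
    return tables


# ---------------------------------------------------------------------------
# Stage runner

STAGES = ("simulate", "preprocess", "align", "categorize", "profile", "stats",
          "discover", "report")


def run_stage(name: str, sim_cfg, run_cfg: RunConfig, workdir: str | Path) -> dict:
    """Execute one named pipeline stage inside ``workdir``.

    Stages communicate through files; each checks that its upstream outputs
    exist and fails naming the stage to run first.  Every stage writes a
    manifest recording parameters and checksums.  Returns the in-memory
    objects the stage produced (handy for the analysis drivers).
    """
    from . import synthetic

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    ref_dir = workdir / "reference"
    data_dir = workdir / "data"
    out_dir = Path(run_cfg.out_dir) if Path(run_cfg.out_dir).is_absolute() \
        else workdir / run_cfg.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    def require(path: Path, produced_by: str) -> Path:
        if not path.exists():
            raise ConfigurationError(
                f"stage {name!r} needs {path.name}; run stage {produced_by!r} first")
        return path

    if name == "simulate":
        reference = synthetic.simulate_reference(sim_cfg)
        paths = synthetic.write_reference(reference, ref_dir)
        run = synthetic.simulate_small_rna_run(sim_cfg, reference, data_dir)
        rnaseq = synthetic.simulate_rnaseq_run(sim_cfg, reference, data_dir)
        write_manifest(workdir / "manifest_simulate.json", "simulate", run_cfg,
                       outputs=[*paths.values(), run.fastq_path])
        return {"reference": reference, "srna": run, "rnaseq": rnaseq}

    if name in ("preprocess", "align", "categorize", "profile"):
        fastq = require(data_dir / "smallrna_multiplexed.fastq", "simulate")
        sheet = read_sample_sheet(require(data_dir / "sample_sheet.tsv", "simulate"))
        barcodes = dict(zip(sheet["barcode"], sheet["sample"]))
        genome = read_fasta(require(ref_dir / "genome.fasta", "simulate"))
        virus = read_fasta(require(ref_dir / "virus.fasta", "simulate"))
        from .features import load_features
        features = load_features(require(ref_dir / "features.gff3", "simulate"))
        analysis = analyze_small_rna(fastq, barcodes, {**genome, **virus},
                                     features, run_cfg)
        outputs = []
        if name == "preprocess":
            path = out_dir / "parse_log.tsv"
            write_table(path, analysis.parse_log.to_frame())
            outputs.append(path)
        elif name == "align":
            rows = [{"sample": s, "mapped": analysis.mapped[s],
                     "unmapped": analysis.unmapped[s]} for s in sorted(analysis.mapped)]
            path = out_dir / "mapping_summary.tsv"
            write_table(path, pd.DataFrame(rows))
            outputs.append(path)
        elif name == "categorize":
            path = out_dir / "category_percentages.tsv"
            write_table(path, analysis.category_frame())
            outputs.append(path)
        else:
            rnaseq_paths = {s: data_dir / f"rnaseq_{s}.fastq" for s in sheet["sample"]}
            rnaseq_paths = {s: p for s, p in rnaseq_paths.items() if p.exists()}
            rnaseq = analyze_rnaseq(rnaseq_paths, {**genome, **virus}, run_cfg)
            attach_rnaseq_normalization(analysis, rnaseq, sheet)
            path = out_dir / "viral_srna_summary.tsv"
            write_table(path, analysis.summary_frame())
            write_table(out_dir / "rnaseq_viral.tsv", rnaseq)
            outputs.append(path)
        write_manifest(workdir / f"manifest_{name}.json", name, run_cfg,
                       inputs=[fastq], outputs=outputs)
        return {"analysis": analysis}

    if name == "stats":
        summary_path = require(out_dir / "viral_srna_summary.tsv", "profile")
        sheet = read_sample_sheet(require(data_dir / "sample_sheet.tsv", "simulate"))
        summary = pd.read_csv(summary_path, sep="\t")
        values = dict(zip(summary["sample"], summary["viral_rpm"]))
        result, letters = compare_genotypes(values, sheet, alpha=run_cfg.alpha)
        path = out_dir / "tukey_viral_rpm.tsv"
        write_table(path, result.pairs)
        write_manifest(workdir / "manifest_stats.json", name, run_cfg,
                       inputs=[summary_path], outputs=[path])
        return {"tukey": result, "letters": letters}

    if name == "discover":
        genome = read_fasta(require(ref_dir / "genome.fasta", "simulate"))
        from .discovery import annotate_virus
        from .formats import iter_fastq
        reads: list[str] = []
        for path in sorted(data_dir.glob("rnaseq_dcl1_*.fastq")) or \
                sorted(data_dir.glob("rnaseq_*.fastq"))[:1]:
            reads.extend(seq for _id, seq, _q in iter_fastq(path))
        contigs, unmapped = discover_virus(reads, genome, run_cfg)
        layout = annotate_virus(contigs[0].sequence) if contigs else None
        rows = [{"rank": i + 1, "length": len(c), "support": c.support,
                 "assigned_fraction": c.assigned_fraction}
                for i, c in enumerate(contigs[:20])]
        path = out_dir / "contig_ranking.tsv"
        write_table(path, pd.DataFrame(rows))
        write_manifest(workdir / "manifest_discover.json", name, run_cfg,
                       outputs=[path])
        return {"contigs": contigs, "layout": layout, "unmapped": unmapped}

    if name == "report":
        raise ConfigurationError(
            "stage 'report' is driven through report_tables(); see analysis/07_report.py")
    raise ConfigurationError(f"unknown stage {name!r}; stages are {STAGES}")
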