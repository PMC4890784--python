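"""Viral small-RNA statistics: RPM scaling, strand ratios, size and 5'-nt
distributions, small-RNA:RNA-seq ratios, per-nucleotide densities, AGO-IP
enrichment.

Conventions
-----------
* RPM = count / library total * 1e6.  The default denominator is the number
  of reads passing preprocessing ("per million of total reads"); mapped-read
  scaling is a config switch in the pipeline layer.
* "Sense" is the viral strand that encodes the ORFs.
* Distributions are percentages and sum to 100 over their support.
* Densities are hit-level (every placement of a multi-mapper contributes);
  totals and percentages are read-level.
* Ratios with a zero denominator are returned as None (an undefined flag),
  never as infinity.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import Hit
from .errors import ConfigurationError

SIZE_RANGE = (18, 30)
BASES = ("A", "C", "G", "U")


def rpm(count: float, total_reads: int) -> float:
    """Reads-per-million scaling of ``count`` against a library total."""
    if total_reads <= 0:
        raise ConfigurationError("RPM denominator (library total) must be > 0")
    return count / total_reads * 1e6


def strand_ratio(sense: float, antisense: float) -> float | None:
    """Sense:antisense ratio; None (undefined) when antisense is zero."""
    if antisense == 0:
        return None
    return sense / antisense


def size_strand_distribution(sense_sizes: Counter, antisense_sizes: Counter,
                             size_range: tuple[int, int] = SIZE_RANGE,
                             ) -> tuple[pd.DataFrame, int]:
    """Percentage of each strand's viral reads at each length.

    Lengths outside ``size_range`` are pooled into the edge bins; the number
    of pooled reads is returned for logging.  A strand with zero reads gets
    an all-NA column (reported empty, never fabricated zeros).
    """
    lo, hi = size_range
    sizes = list(range(lo, hi + 1))
    out = pd.DataFrame(index=pd.Index(sizes, name="size"),
                       columns=["sense", "antisense"], dtype=float)
    pooled = 0
    for strand, counter in (("sense", sense_sizes), ("antisense", antisense_sizes)):
        total = sum(counter.values())
        if total == 0:
            continue
        binned = Counter()
        for size, n in counter.items():
            clipped = min(max(size, lo), hi)
            if clipped != size:
                pooled += n
            binned[clipped] += n
        for size in sizes:
            out.loc[size, strand] = 100.0 * binned.get(size, 0) / total
    return out, pooled


def five_prime_distribution(first_bases: Counter) -> dict[str, float]:
    """Percentage of viral reads starting with each base (DNA T reported as U)."""
    total = sum(first_bases.values())
    if total == 0:
        raise ConfigurationError("no viral reads: 5' distribution undefined")
    merged = Counter()
    for base, n in first_bases.items():
        merged["U" if base.upper() in ("T", "U") else base.upper()] += n
    return {b: 100.0 * merged.get(b, 0) / total for b in BASES}


def sr_to_rnaseq_ratio(srna_rpms: Sequence[float], rnaseq_mean_rpm: float,
                       ) -> tuple[list[float], float] | None:
    """Per-replicate small-RNA RPM divided by the genotype's mean RNA-seq RPM.

    Returns ``(per-replicate ratios, their mean)``; None when the RNA-seq
    mean is zero (undefined).
    """
    if rnaseq_mean_rpm <= 0:
        return None
    ratios = [x / rnaseq_mean_rpm for x in srna_rpms]
    return ratios, float(np.mean(ratios))


def per_nt_density(hits_with_counts: Iterable[tuple[Hit, int]], contig: str,
                   contig_length: int, strand: str, total_reads: int,
                   normalizer: float | None = None) -> np.ndarray:
    """Per-position coverage of one strand of one contig, in RPM.

    Every placement of a multi-mapping read contributes (hit-level counting).
    If ``normalizer`` is given (the genotype's strand-mean RNA-seq RPM),
    every position is divided by it; a non-positive normalizer raises, the
    caller should treat that genotype/strand as undefined.
    """
    if normalizer is not None and normalizer <= 0:
        raise ConfigurationError("density normalizer must be > 0 (undefined otherwise)")
    density = np.zeros(contig_length)
    for hit, mult in hits_with_counts:
        if hit.contig != contig or hit.strand != strand:
            continue
        density[hit.start:hit.end] += mult
    density = density / total_reads * 1e6
    if normalizer is not None:
        density = density / normalizer
    return density


def density_to_gff(density: np.ndarray, contig: str, strand: str,
                   source: str = "vsrna"):
    """Per-nucleotide density as GFF3-style coverage records (1-based)."""
    from .formats import GffRecord
    return [GffRecord(contig, source, "coverage", i + 1, i + 1,
                      f"{value:.6g}", strand, ".", {"ID": f"{contig}_{strand}_{i + 1}"})
            for i, value in enumerate(density) if value > 0]


@dataclass
class IPEnrichment:
    """Comparison of an AGO IP against its input fraction."""

    pearson_r: float | None
    n_sequences: int                 # union of unique sequences
    viral_rpm_difference: float | None
    table: pd.DataFrame = field(repr=False, default=None)


def ip_enrichment(input_counts: Counter, ip_counts: Counter,
                  input_viral_rpm: float | None = None,
                  ip_viral_rpm: float | None = None,
                  log_transform: bool = False) -> IPEnrichment:
    """Join unique-sequence counts across input and IP and correlate them.

    Outer join with absent sequences as zero; Pearson r on the raw counts
    (optionally log1p-transformed).  r is undefined (None) with fewer than
    3 shared unique sequences.
    """
    union = sorted(set(input_counts) | set(ip_counts))
    table = pd.DataFrame({
        "sequence": union,
        "input": [input_counts.get(s, 0) for s in union],
        "ip": [ip_counts.get(s, 0) for s in union],
    })
    shared = int(((table["input"] > 0) & (table["ip"] > 0)).sum())
    if shared < 3:
        r = None
    else:
        x, y = table["input"].to_numpy(float), table["ip"].to_numpy(float)
        if log_transform:
            x, y = np.log1p(x), np.log1p(y)
        r = float(stats.pearsonr(x, y).statistic)
        if math.isnan(r):
            r = None
    diff = None
    if input_viral_rpm is not None and ip_viral_rpm is not None:
        diff = ip_viral_rpm - input_viral_rpm
    return IPEnrichment(pearson_r=r, n_sequences=len(union),
                        viral_rpm_difference=diff, table=table)


@dataclass
class ViralProfile:
    """All per-sample viral small-RNA statistics for one library."""

    sample: str
    total_reads: int
    viral_reads: int
    sense_reads: int
    antisense_reads: int
    sense_rpm: float
    antisense_rpm: float
    ratio_sense_antisense: float | None
    size_by_strand: pd.DataFrame = field(repr=False, default=None)
    five_prime: dict[str, float] = field(default_factory=dict)
    per_nt_sense: np.ndarray = field(repr=False, default=None)
    per_nt_antisense: np.ndarray = field(repr=False, default=None)
    sr_to_rnaseq: float | None = None

    @property
    def viral_rpm(self) -> float:
        return rpm(self.viral_reads, self.total_reads)

    def summary_row(self) -> dict:
        return {
            "sample": self.sample,
            "total_reads": self.total_reads,
            "viral_reads": self.viral_reads,
            "viral_rpm": self.viral_rpm,
            "sense_rpm": self.sense_rpm,
            "antisense_rpm": self.antisense_rpm,
            "ratio_sense_antisense": (np.nan if self.ratio_sense_antisense is None
                                      else self.ratio_sense_antisense),
            "pct_5pU": self.five_prime.get("U", np.nan),
            "sr_to_rnaseq": (np.nan if self.sr_to_rnaseq is None
                             else self.sr_to_rnaseq),
        }
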