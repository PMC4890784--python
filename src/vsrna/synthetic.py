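"""Synthetic reference, small-RNA and RNA-seq data with the statistical
structure the analysis assumes.

The generator emulates a multiplexed fungal small-RNA experiment carrying a
non-segmented dsRNA mycovirus: per-genotype viral small-RNA abundance,
sense:antisense strand bias, size preference over 18-30 nt, 5'-nucleotide
preference, optional per-nucleotide hotspots, contamination of DCL-deficient
genotypes with viral mRNA degradation fragments, and strand-specific RNA-seq
with a minus-strand (dsRNA replicative) component.  Every read's true origin
is recorded in a truth table so each downstream stage can be checked against
a known answer.

Randomness: one top-level seed; each library draws from a child stream keyed
on (seed, sample name), so adding a sample never perturbs the others.
Quality strings are constant — the parser is sequence-only.
"""

from __future__ import annotations

import itertools
import zlib
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .align import revcomp
from .errors import ConfigurationError
from .features import CATEGORY_PRIORITY, Feature, FeatureSet
from .formats import GffRecord, write_fasta, write_fastq, write_gff3

SIZES = tuple(range(18, 31))
DNA = "ACGT"
VIRUS_CONTIG = "virus"
STOPS = ("TAA", "TAG", "TGA")
_PMF_TOL = 1e-9


def _child_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _check_pmf(name: str, pmf: dict, keys: tuple) -> None:
    if set(pmf) != set(keys):
        raise ConfigurationError(f"{name}: support must be exactly {keys}")
    values = list(pmf.values())
    if any(v < 0 or v > 1 for v in values):
        raise ConfigurationError(f"{name}: probabilities must lie in [0, 1]")
    if abs(sum(values) - 1.0) > _PMF_TOL:
        raise ConfigurationError(f"{name}: probabilities sum to {sum(values)}, not 1")


# --------------------------------------------------------------------------
# Default statistical profiles (one per genotype class)

CONTROL_SIZE_PMF = dict(zip(SIZES, (0.01, 0.02, 0.13, 0.42, 0.20, 0.10, 0.07,
                                    0.02, 0.01, 0.01, 0.005, 0.003, 0.002)))
#: DCL-loss: 21-nt class depleted, >=23 nt enriched, overall broad
DCL_LOSS_SIZE_PMF = dict(zip(SIZES, (0.04, 0.05, 0.08, 0.08, 0.09, 0.13, 0.14,
                                     0.12, 0.10, 0.07, 0.05, 0.03, 0.02)))
AGO_LOSS_SIZE_PMF = dict(zip(SIZES, (0.01, 0.02, 0.12, 0.36, 0.19, 0.12, 0.09,
                                     0.04, 0.02, 0.015, 0.01, 0.003, 0.002)))

CONTROL_5P_PMF = {"A": 0.12, "C": 0.06, "G": 0.07, "U": 0.75}
DCL_LOSS_5P_PMF = {"A": 0.30, "C": 0.22, "G": 0.23, "U": 0.25}
AGO_LOSS_5P_PMF = {"A": 0.25, "C": 0.14, "G": 0.16, "U": 0.45}


@dataclass
class GenotypeProfile:
    """Generative law for one genotype's libraries.

    ``sense_fraction`` is the probability that a *true* viral siRNA comes
    from the ORF-encoding (plus) strand; ``degradation_fraction`` is the
    probability that a nominally viral small RNA is instead a random
    plus-strand mRNA fragment (18-30 nt, unbiased 5' nt) — the contamination
    mode of DCL-deficient strains.
    """

    name: str
    n_replicates: int = 4
    viral_fraction_srna: float = 0.04666
    sense_fraction: float = 0.597
    size_pmf: dict[int, float] = field(default_factory=lambda: dict(CONTROL_SIZE_PMF))
    five_prime_pmf: dict[str, float] = field(default_factory=lambda: dict(CONTROL_5P_PMF))
    hotspot_weights: dict[str, np.ndarray] | None = None  # per strand, else uniform
    degradation_fraction: float = 0.0
    decoy_fraction: float = 0.005
    rnaseq_viral_fraction: float = 0.002
    rnaseq_antisense_fraction: float = 0.05
    rnaseq_decoy_fraction: float = 0.005
    fraction: str = "total"  # sample-sheet fraction: total, IP-input, IP

    def validate(self, virus_length: int) -> None:
        for attr in ("viral_fraction_srna", "sense_fraction", "degradation_fraction",
                     "decoy_fraction", "rnaseq_viral_fraction",
                     "rnaseq_antisense_fraction", "rnaseq_decoy_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"genotype {self.name}: {attr}={v} not in [0, 1]")
        if self.viral_fraction_srna + self.decoy_fraction > 1:
            raise ConfigurationError(
                f"genotype {self.name}: viral + decoy fractions exceed 1")
        if self.n_replicates < 1:
            raise ConfigurationError(f"genotype {self.name}: n_replicates < 1")
        _check_pmf(f"genotype {self.name}: size_pmf", self.size_pmf, SIZES)
        _check_pmf(f"genotype {self.name}: five_prime_pmf", self.five_prime_pmf,
                   ("A", "C", "G", "U"))
        if self.hotspot_weights is not None:
            for strand, w in self.hotspot_weights.items():
                w = np.asarray(w, dtype=float)
                if strand not in "+-" or len(w) != virus_length or (w < 0).any():
                    raise ConfigurationError(
                        f"genotype {self.name}: hotspot_weights[{strand}] invalid")


def default_genotypes(n_replicates: int = 4) -> list[GenotypeProfile]:
    """The default eight-genotype silencing-mutant design.

    Controls and the rdr/dcl2 mutants share one law (sense:antisense 1.48,
    75% 5'U, 21-nt peak, sRNA:RNA-seq ~ 23.3).  dcl1 and dcl1dcl2 lose size
    and 5'-nt specificity and gain sense bias through mRNA degradation
    fragments; ago1 over-accumulates viral siRNA while viral RNA rises, so
    its sRNA:RNA-seq ratio collapses to ~0.9.
    """
    control_like = dict(viral_fraction_srna=0.04666, sense_fraction=0.597,
                        rnaseq_viral_fraction=0.002)
    genotypes = [GenotypeProfile(name=n, n_replicates=n_replicates, **control_like)
                 for n in ("control", "rdr1", "rdr2", "rdr3", "dcl2")]
    # DCL-loss sense_fraction values are for the true-siRNA component; the
    # observed ratios (after the plus-strand degradation admixture) are
    # (1-g)s+g over 1-((1-g)s+g), i.e. ~3.7 for dcl1 and ~9.5 for dcl1dcl2.
    genotypes.append(GenotypeProfile(
        name="dcl1", n_replicates=n_replicates, viral_fraction_srna=0.056,
        sense_fraction=0.574, size_pmf=dict(DCL_LOSS_SIZE_PMF),
        five_prime_pmf=dict(DCL_LOSS_5P_PMF), degradation_fraction=0.5,
        rnaseq_viral_fraction=0.2, rnaseq_antisense_fraction=0.012,
        rnaseq_decoy_fraction=0.053))
    genotypes.append(GenotypeProfile(
        name="dcl1dcl2", n_replicates=n_replicates, viral_fraction_srna=0.03,
        sense_fraction=0.683, size_pmf=dict(DCL_LOSS_SIZE_PMF),
        five_prime_pmf=dict(DCL_LOSS_5P_PMF), degradation_fraction=0.7,
        rnaseq_viral_fraction=0.5, rnaseq_antisense_fraction=0.012))
    genotypes.append(GenotypeProfile(
        name="ago1", n_replicates=n_replicates, viral_fraction_srna=0.28,
        sense_fraction=0.597, size_pmf=dict(AGO_LOSS_SIZE_PMF),
        five_prime_pmf=dict(AGO_LOSS_5P_PMF), degradation_fraction=0.02,
        rnaseq_viral_fraction=0.311, rnaseq_antisense_fraction=0.03))
    return genotypes


DEFAULT_FEATURE_SPEC = {
    "structural_rna": (4, (120, 200)),
    "mitochondrial": (2, (300, 500)),
    "transposable_element": (6, (200, 400)),
    "repeat": (8, (80, 150)),
    "protein_coding": (20, (300, 600)),
}


@dataclass
class SimConfig:
    """Full description of one synthetic experiment."""

    seed: int = 0
    contig_lengths: tuple[int, ...] = (12000, 10000, 8000)
    feature_spec: dict[str, tuple[int, tuple[int, int]]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_SPEC))
    virus_length: int = 2923
    orf1_span: tuple[int, int] = (17, 991)
    orf2_span: tuple[int, int] = (1081, 2817)
    slippery_heptamer: str | None = "GGATTTT"
    genotypes: list[GenotypeProfile] = field(default_factory=default_genotypes)
    reads_per_library: int = 20000
    rnaseq_reads_per_library: int = 20000
    rnaseq_read_length: int = 50
    read_length: int = 50
    adapter: str = "CTGTAG"
    barcode_length: int = 5
    barcode_map: dict[str, str] | None = None  # sample -> barcode; generated if None

    def validate(self) -> None:
        for span_name in ("orf1_span", "orf2_span"):
            start, end = getattr(self, span_name)
            if not (1 <= start <= end <= self.virus_length):
                raise ConfigurationError(f"{span_name}={start, end} outside virus")
            length = end - start + 1
            if length < 6:
                raise ConfigurationError(
                    f"{span_name}: ORF of {length} nt cannot hold ATG + stop")
            if length % 3:
                raise ConfigurationError(f"{span_name}: length {length} not divisible by 3")
        if self.orf1_span[1] >= self.orf2_span[0]:
            raise ConfigurationError("orf1_span and orf2_span overlap or are unordered")
        if self.slippery_heptamer is not None:
            hept = self.slippery_heptamer.upper().replace("U", "T")
            if len(hept) != 7 or any(b not in DNA for b in hept):
                raise ConfigurationError("slippery_heptamer: must be a 7-mer over ACGU/T")
            if self.orf1_span[1] - self.orf1_span[0] + 1 < 3 + 7 + 3:
                raise ConfigurationError(
                    "slippery_heptamer: ORF1 too short to hold start + heptamer + stop")
        if len(self.adapter) < 4:
            raise ConfigurationError("adapter: must be at least 4 nt")
        if self.reads_per_library < 0 or self.rnaseq_reads_per_library < 0:
            raise ConfigurationError("reads_per_library: must be >= 0")
        for profile in self.genotypes:
            profile.validate(self.virus_length)

    def samples(self) -> list[tuple[str, GenotypeProfile, int]]:
        out = []
        for profile in self.genotypes:
            for rep in range(1, profile.n_replicates + 1):
                out.append((f"{profile.name}_r{rep}", profile, rep))
        return out

    def barcodes(self) -> dict[str, str]:
        """sample -> barcode; fixed length, distinct, hence prefix-free."""
        if self.barcode_map is not None:
            return dict(self.barcode_map)
        names = [s for s, _, _ in self.samples()]
        pool = ["".join(p) for p in itertools.product(DNA, repeat=self.barcode_length)]
        if len(names) > len(pool):
            raise ConfigurationError(
                f"barcode_length={self.barcode_length} cannot index {len(names)} samples")
        step = max(1, len(pool) // max(len(names), 1))
        return {name: pool[i * step] for i, name in enumerate(names)}


# --------------------------------------------------------------------------
# Reference generation


@dataclass
class SyntheticReference:
    genome: dict[str, str]          # host contigs only
    virus: str
    features: FeatureSet            # includes the viral feature on VIRUS_CONTIG

    @property
    def expanded(self) -> dict[str, str]:
        """Host contigs plus the viral contig — the post-discovery reference."""
        return {**self.genome, VIRUS_CONTIG: self.virus}


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(DNA), size=length))


def _forbidden_patterns(adapter: str) -> tuple[str, str]:
    # reads from the minus strand carry revcomp(genome); screen both senses
    return adapter, revcomp(adapter)


def _screen_host_contig(seq: list[str], rng: np.random.Generator, adapter: str) -> None:
    text = "".join(seq)
    for pattern in _forbidden_patterns(adapter):
        start = text.find(pattern)
        while start != -1:
            mid = start + len(pattern) // 2
            choices = [b for b in DNA if b != seq[mid]]
            seq[mid] = choices[rng.integers(len(choices))]
            text = "".join(seq)
            start = text.find(pattern)


def _build_virus(cfg: SimConfig, rng: np.random.Generator) -> str:
    seq = _random_seq(rng, cfg.virus_length)
    protected: set[int] = set()

    def write(pos0: int, bases: str) -> None:
        for i, b in enumerate(bases):
            seq[pos0 + i] = b
            protected.add(pos0 + i)

    for span in (cfg.orf1_span, cfg.orf2_span):
        start0, end0 = span[0] - 1, span[1] - 1
        write(start0, "ATG")
        for codon_start in range(start0 + 3, end0 - 2, 3):
            codon = "".join(rng.choice(list(DNA), size=3))
            while codon in STOPS:
                codon = "".join(rng.choice(list(DNA), size=3))
            seq[codon_start:codon_start + 3] = list(codon)
        write(end0 - 2, STOPS[rng.integers(3)])
    if cfg.slippery_heptamer is not None:
        hept = cfg.slippery_heptamer.upper().replace("U", "T")
        # heptamer's last base abuts the ORF1 stop codon
        write(cfg.orf1_span[1] - 1 - 3 - 6, hept)

    def first_problem() -> tuple[int, int] | None:
        """(start0, end0_exclusive) of the first constraint violation."""
        text = "".join(seq)
        # internal in-frame stops
        for span in (cfg.orf1_span, cfg.orf2_span):
            for codon_start in range(span[0] - 1, span[1] - 3, 3):
                if text[codon_start:codon_start + 3] in STOPS:
                    return codon_start, codon_start + 3
        # an in-frame ATG upstream of a declared start with no intervening
        # stop would shift the maximal ORF; forbid it
        for span in (cfg.orf1_span, cfg.orf2_span):
            start0 = span[0] - 1
            pos = start0 - 3
            while pos >= 0:
                codon = text[pos:pos + 3]
                if codon in STOPS:
                    break
                if codon == "ATG":
                    return pos, pos + 3
                pos -= 3
        # adapter sequence anywhere (either sense) breaks read parsing
        for pattern in _forbidden_patterns(cfg.adapter):
            at = text.find(pattern)
            if at != -1:
                return at, at + len(pattern)
        return None

    for _ in range(2000):
        problem = first_problem()
        if problem is None:
            break
        start0, end0 = problem
        free = [i for i in range(start0, end0) if i not in protected]
        if not free:
            raise ConfigurationError(
                "virus constraints conflict inside a protected region "
                "(orf spans / slippery_heptamer)")
        i = free[rng.integers(len(free))]
        choices = [b for b in DNA if b != seq[i]]
        seq[i] = choices[rng.integers(len(choices))]
    else:
        raise ConfigurationError("could not satisfy virus sequence constraints")
    return "".join(seq)


def simulate_reference(cfg: SimConfig) -> SyntheticReference:
    """Generate host contigs, a feature annotation, and the viral genome.

    Deterministic in ``cfg.seed``.  ORFs are guaranteed to be the maximal
    ORFs of their frames (ATG start, single terminal stop, no internal or
    upstream-extending starts), and the slippery heptamer (if any) sits with
    its last base immediately 5' of the ORF1 stop codon.
    """
    cfg.validate()
    rng = _child_rng(cfg.seed, "reference")
    genome: dict[str, str] = {}
    for i, length in enumerate(cfg.contig_lengths, start=1):
        seq = _random_seq(rng, length)
        _screen_host_contig(seq, rng, cfg.adapter)
        genome[f"contig{i}"] = "".join(seq)

    features = FeatureSet()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    contig_names = list(genome)
    counter = 0
    for category in sorted(cfg.feature_spec):
        count, (lo, hi) = cfg.feature_spec[category]
        if category not in CATEGORY_PRIORITY or category in ("viral", "non_annotated"):
            raise ConfigurationError(f"feature_spec: cannot place category {category!r}")
        for _ in range(count):
            length = int(rng.integers(lo, hi + 1))
            for _attempt in range(200):
                contig = contig_names[rng.integers(len(contig_names))]
                max_start = len(genome[contig]) - length
                if max_start < 0:
                    continue
                start0 = int(rng.integers(0, max_start + 1))
                span = (start0, start0 + length)
                if all(span[1] <= s or span[0] >= e for s, e in occupied[contig]):
                    occupied[contig].append(span)
                    counter += 1
                    strand = "+" if rng.random() < 0.5 else "-"
                    features.add(Feature(contig, start0 + 1, start0 + length,
                                         strand, category, f"{category}_{counter}"))
                    break
            else:
                raise ConfigurationError(
                    f"feature_spec: cannot place {category} of {length} nt "
                    "without overlap; reduce counts or lengths")

    virus = _build_virus(cfg, rng)
    features.add(Feature(VIRUS_CONTIG, 1, len(virus), "+", "viral", VIRUS_CONTIG))
    return SyntheticReference(genome=genome, virus=virus, features=features)


def features_to_gff(reference: SyntheticReference) -> list[GffRecord]:
    return [GffRecord(f.contig, "synthetic", "region", f.start, f.end, ".",
                      f.strand, ".", {"ID": f.feature_id, "category": f.category})
            for f in reference.features.features]


def write_reference(reference: SyntheticReference, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": out_dir / "genome.fasta", "virus": out_dir / "virus.fasta",
             "features": out_dir / "features.gff3"}
    write_fasta(paths["genome"], reference.genome)
    write_fasta(paths["virus"], {VIRUS_CONTIG: reference.virus})
    write_gff3(paths["features"], features_to_gff(reference))
    return paths


# --------------------------------------------------------------------------
# Small-RNA libraries


TRUTH_COLUMNS = ["sample", "origin", "category", "strand", "contig",
                 "position", "length", "first_base"]


def _viral_start_table(virus: str, profile: GenotypeProfile,
                       cache: dict) -> dict[tuple[str, int, str], tuple[np.ndarray, np.ndarray]]:
    """(strand, length, 5'-base) -> (candidate starts, sampling probabilities).

    A read's 5' base is realised by conditioning the start position on it, so
    emitted reads are verbatim genome substrings (perfect-match compatible)
    while the 5'-nt distribution matches the configured PMF exactly.
    """
    key = id(profile.hotspot_weights)
    if key in cache:
        return cache[key]
    comp = str.maketrans(DNA, "TGCA")
    arr = np.frombuffer(virus.encode(), dtype="S1").astype("U1")
    table = {}
    n = len(virus)
    for strand in "+-":
        if profile.hotspot_weights is not None:
            weights = np.asarray(profile.hotspot_weights[strand], dtype=float)
        else:
            weights = np.ones(n)
        for length in SIZES:
            starts_all = np.arange(n - length + 1)
            if strand == "+":
                first = arr[starts_all]
            else:  # 5' base of a minus-strand read = complement of the 3'-most base
                first = np.array([b.translate(comp) for b in arr[starts_all + length - 1]])
            for base in DNA:
                starts = starts_all[first == base]
                w = weights[starts]
                total = w.sum()
                if len(starts) and total > 0:
                    table[(strand, length, base)] = (starts, w / total)
    cache[key] = table
    return table


def _sample_decoys(rng: np.random.Generator, lengths: Iterable[int],
                   reference: SyntheticReference, adapter: str = "CTGTAG") -> list[str]:
    expanded = reference.expanded
    decoys = []
    for length in lengths:
        while True:
            seq = "".join(rng.choice(list(DNA), size=int(length)))
            rc = revcomp(seq)
            if any(p in seq or p in rc for p in _forbidden_patterns(adapter)):
                continue
            if not any(seq in c or rc in c for c in expanded.values()):
                decoys.append(seq)
                break
    return decoys


_FILLER = "GCACCATCAAT" * 8  # post-barcode filler; contains no adapter


@dataclass
class SmallRnaRun:
    fastq_path: Path
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame
    barcodes: dict[str, str]        # barcode -> sample (parser orientation)


def _origin_category(reference: SyntheticReference, contig: str,
                     start0: int, length: int) -> str:
    feats = reference.features.overlapping(contig, start0, start0 + length)
    found = {f.category for f in feats}
    for cat in CATEGORY_PRIORITY:
        if cat in found:
            return cat
    return "non_annotated"


def _simulate_viral_srna(rng: np.random.Generator, profile: GenotypeProfile,
                         virus: str, n: int, start_tables: dict) -> list[tuple[str, str, int]]:
    """n true siRNAs as (sequence, strand, start0), PMF-exact by construction."""
    table = start_tables
    strands = np.where(rng.random(n) < profile.sense_fraction, "+", "-")
    sizes = rng.choice(SIZES, size=n, p=[profile.size_pmf[s] for s in SIZES])
    base_order = ("A", "C", "G", "U")
    bases = rng.choice(["A", "C", "G", "T"], size=n,
                       p=[profile.five_prime_pmf[b] for b in base_order])
    reads: list[tuple[str, str, int] | None] = [None] * n
    order = np.lexsort((bases, sizes, strands))
    i = 0
    while i < len(order):
        j = i
        key = (strands[order[i]], int(sizes[order[i]]), bases[order[i]])
        while j < len(order) and (strands[order[j]], int(sizes[order[j]]),
                                  bases[order[j]]) == key:
            j += 1
        group = order[i:j]
        if key not in table:
            raise ConfigurationError(
                f"no viral start position available for strand={key[0]} "
                f"length={key[1]} first_base={key[2]} under the hotspot weights")
        starts, probs = table[key]
        chosen = rng.choice(starts, size=len(group), p=probs)
        strand, length = key[0], key[1]
        for idx, start0 in zip(group, chosen):
            window = virus[start0:start0 + length]
            seq = window if strand == "+" else revcomp(window)
            reads[idx] = (seq, strand, int(start0))
        i = j
    return reads  # type: ignore[return-value]


def simulate_small_rna_run(cfg: SimConfig, reference: SyntheticReference,
                           out_dir: str | Path) -> SmallRnaRun:
    """One multiplexed small-RNA FASTQ + sample sheet + per-read truth table."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sample_barcodes = cfg.barcodes()
    samples = cfg.samples()
    sheet = pd.DataFrame(
        [(name, sample_barcodes[name], prof.name, rep, prof.fraction)
         for name, prof, rep in samples],
        columns=["sample", "barcode", "genotype", "replicate", "fraction"])
    if sheet["barcode"].duplicated().any():
        raise ConfigurationError("barcode_map: duplicate barcodes across samples")

    virus = reference.virus
    contig_names = sorted(reference.genome)
    contig_lens = np.array([len(reference.genome[c]) for c in contig_names], dtype=float)
    contig_probs = contig_lens / contig_lens.sum()
    start_cache: dict = {}

    fastq_path = out_dir / "smallrna_multiplexed.fastq"
    truth_frames = []
    with open(fastq_path, "w") as fq:
        for name, profile, _rep in samples:
            rng = _child_rng(cfg.seed, f"srna:{name}")
            n = cfg.reads_per_library
            p_sirna = profile.viral_fraction_srna * (1 - profile.degradation_fraction)
            p_degr = profile.viral_fraction_srna * profile.degradation_fraction
            p_decoy = profile.decoy_fraction
            p_host = 1.0 - p_sirna - p_degr - p_decoy
            n_sirna, n_degr, n_host, n_decoy = rng.multinomial(
                n, [p_sirna, p_degr, p_host, p_decoy])

            rows = []  # (origin, category, strand, contig, pos0, length, first)
            inserts = []
            tables = _viral_start_table(virus, profile, start_cache)
            for seq, strand, start0 in _simulate_viral_srna(rng, profile, virus,
                                                            int(n_sirna), tables):
                inserts.append(seq)
                rows.append(("sirna", "viral", strand, VIRUS_CONTIG, start0,
                             len(seq), seq[0]))
            degr_lengths = rng.integers(SIZES[0], SIZES[-1] + 1, size=int(n_degr))
            for length in degr_lengths:
                start0 = int(rng.integers(0, len(virus) - length + 1))
                seq = virus[start0:start0 + int(length)]
                inserts.append(seq)
                rows.append(("degradation", "viral", "+", VIRUS_CONTIG, start0,
                             int(length), seq[0]))
            host_contigs = rng.choice(len(contig_names), size=int(n_host), p=contig_probs)
            host_lengths = rng.choice(SIZES, size=int(n_host),
                                      p=[profile.size_pmf[s] for s in SIZES])
            host_strands = np.where(rng.random(int(n_host)) < 0.5, "+", "-")
            for ci, length, strand in zip(host_contigs, host_lengths, host_strands):
                contig = contig_names[ci]
                cseq = reference.genome[contig]
                start0 = int(rng.integers(0, len(cseq) - int(length) + 1))
                window = cseq[start0:start0 + int(length)]
                seq = window if strand == "+" else revcomp(window)
                category = _origin_category(reference, contig, start0, int(length))
                inserts.append(seq)
                rows.append(("host", category, strand, contig, start0,
                             int(length), seq[0]))
            decoy_lengths = rng.choice(SIZES, size=int(n_decoy),
                                       p=[profile.size_pmf[s] for s in SIZES])
            for seq in _sample_decoys(rng, decoy_lengths, reference, cfg.adapter):
                inserts.append(seq)
                rows.append(("decoy", "unmapped", ".", ".", -1, len(seq), seq[0]))

            order = rng.permutation(len(inserts))
            barcode = sample_barcodes[name]
            for out_i, idx in enumerate(order):
                insert = inserts[idx]
                raw = (insert + cfg.adapter + barcode + _FILLER)[:cfg.read_length]
                fq.write(f"@{name}:{out_i}\n{raw}\n+\n{'I' * len(raw)}\n")
            frame = pd.DataFrame([rows[idx] for idx in order],
                                 columns=["origin", "category", "strand", "contig",
                                          "position", "length", "first_base"])
            frame.insert(0, "sample", name)
            truth_frames.append(frame)

    truth = (pd.concat(truth_frames, ignore_index=True) if truth_frames
             else pd.DataFrame(columns=TRUTH_COLUMNS))
    sheet_path = out_dir / "sample_sheet.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)
    truth.to_csv(out_dir / "smallrna_truth.tsv", sep="\t", index=False)
    return SmallRnaRun(fastq_path=fastq_path, sample_sheet=sheet, truth=truth,
                       barcodes={b: s for s, b in sample_barcodes.items()})


# --------------------------------------------------------------------------
# RNA-seq libraries


@dataclass
class RnaSeqRun:
    fastq_paths: dict[str, Path]
    truth: pd.DataFrame


def simulate_rnaseq_run(cfg: SimConfig, reference: SyntheticReference,
                        out_dir: str | Path) -> RnaSeqRun:
    """Per-sample strand-specific RNA-seq FASTQ files + truth table.

    Fixed-length reads; a read's sequence is the template-strand sequence
    (minus-strand viral reads are reverse-complemented genome windows), so
    orientation encodes the strand of origin.
    """
    cfg.validate()
    read_len = cfg.rnaseq_read_length
    shortest = min(min(len(s) for s in reference.genome.values()), len(reference.virus))
    if read_len > shortest:
        raise ConfigurationError(
            f"rnaseq_read_length={read_len} exceeds shortest contig ({shortest} nt)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    virus = reference.virus
    contig_names = sorted(reference.genome)
    contig_lens = np.array([len(reference.genome[c]) for c in contig_names], dtype=float)
    contig_probs = contig_lens / contig_lens.sum()

    fastq_paths = {}
    truth_frames = []
    for name, profile, _rep in cfg.samples():
        rng = _child_rng(cfg.seed, f"rnaseq:{name}")
        n = cfg.rnaseq_reads_per_library
        p_v, p_d = profile.rnaseq_viral_fraction, profile.rnaseq_decoy_fraction
        n_viral, n_host, n_decoy = rng.multinomial(n, [p_v, 1 - p_v - p_d, p_d])
        records = []
        rows = []
        for _ in range(int(n_viral)):
            start0 = int(rng.integers(0, len(virus) - read_len + 1))
            minus = rng.random() < profile.rnaseq_antisense_fraction
            window = virus[start0:start0 + read_len]
            seq = revcomp(window) if minus else window
            records.append(seq)
            rows.append(("viral", "-" if minus else "+", VIRUS_CONTIG, start0))
        host_contigs = rng.choice(len(contig_names), size=int(n_host), p=contig_probs)
        for ci in host_contigs:
            contig = contig_names[ci]
            cseq = reference.genome[contig]
            start0 = int(rng.integers(0, len(cseq) - read_len + 1))
            records.append(cseq[start0:start0 + read_len])
            rows.append(("host", "+", contig, start0))
        for seq in _sample_decoys(rng, [read_len] * int(n_decoy), reference, cfg.adapter):
            records.append(seq)
            rows.append(("decoy", ".", ".", -1))

        order = rng.permutation(len(records))
        path = out_dir / f"rnaseq_{name}.fastq"
        write_fastq(path, ((f"{name}:{i}", records[idx], "I" * len(records[idx]))
                           for i, idx in enumerate(order)))
        fastq_paths[name] = path
        frame = pd.DataFrame([rows[idx] for idx in order],
                             columns=["origin", "strand", "contig", "position"])
        frame.insert(0, "sample", name)
        truth_frames.append(frame)
    truth = (pd.concat(truth_frames, ignore_index=True) if truth_frames
             else pd.DataFrame(columns=["sample", "origin", "strand", "contig", "position"]))
    truth.to_csv(out_dir / "rnaseq_truth.tsv", sep="\t", index=False)
    return RnaSeqRun(fastq_paths=fastq_paths, truth=truth)


# --------------------------------------------------------------------------
# Analytic oracle for recovered statistics


def degradation_first_base_pmf(virus: str) -> dict[str, float]:
    """First-base law of uniform plus-strand fragments (length uniform 18-30)."""
    totals = Counter()
    n = len(virus)
    for length in SIZES:
        prefix = virus[:n - length + 1]
        denom = (n - length + 1) * len(SIZES)
        for base in DNA:
            totals[base] += prefix.count(base) / denom
    return dict(totals)


def expected_observed_profile(profile: GenotypeProfile, virus: str) -> dict:
    """Expected *observed* viral-read statistics, degradation included.

    The configured PMFs describe true siRNAs only; what the pipeline sees is
    the mixture with the uniform plus-strand fragment law.  This closed form
    is the oracle the recovery tests compare against.
    """
    g = profile.degradation_fraction
    sense = (1 - g) * profile.sense_fraction + g * 1.0
    degr5p = degradation_first_base_pmf(virus)
    rna = {"A": "A", "C": "C", "G": "G", "T": "U"}
    five_prime = {rna[b]: (1 - g) * profile.five_prime_pmf[rna[b]] + g * degr5p[b]
                  for b in DNA}
    size_pmf = {s: (1 - g) * profile.size_pmf[s] + g / len(SIZES) for s in SIZES}
    return {"sense_fraction": sense, "five_prime": five_prime, "size_pmf": size_pmf,
            "viral_fraction": profile.viral_fraction_srna}


def ip_experiment_genotypes(n_replicates: int = 3) -> list[GenotypeProfile]:
    """An AGO-IP design: input fraction vs an IP retaining 5'U 21-nt siRNAs."""
    base = GenotypeProfile(name="ago1ip_input", n_replicates=n_replicates,
                           fraction="IP-input")
    ip = replace(base, name="ago1ip", fraction="IP", viral_fraction_srna=0.25,
                 five_prime_pmf={"A": 0.004, "C": 0.003, "G": 0.003, "U": 0.99},
                 sense_fraction=0.565,  # ratio ~1.3 in the IP
                 size_pmf=dict(CONTROL_SIZE_PMF))
    return [base, ip]
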