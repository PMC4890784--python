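"""Feature catalogue: interval annotations, read categorisation, per-feature
strand counts.

Categories form a closed set with a fixed priority used to give every mapped
read a single category even when its hits touch several feature classes
(viral wins over everything, then structural RNA, mitochondrial, TE, repeat,
protein-coding; reads touching nothing are non_annotated).  Category/feature
counting is read-level — a read counts once no matter how many placements it
has — so category percentages sum to 100.  Hit-level counting is reserved
for per-nucleotide densities (see profiling).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from intervaltree import IntervalTree

from .align import Hit
from .errors import ConfigurationError, FormatError
from .formats import GffRecord, read_bed, read_gff3

CATEGORIES = ("viral", "structural_rna", "mitochondrial", "transposable_element",
              "repeat", "protein_coding", "non_annotated")

#: default priority, highest first; non_annotated is the implicit complement
CATEGORY_PRIORITY = CATEGORIES


class Feature(NamedTuple):
    contig: str
    start: int      # 1-based inclusive
    end: int        # 1-based inclusive
    strand: str
    category: str
    feature_id: str


@dataclass
class FeatureSet:
    """Categorised intervals with stabbing-query support.

    ``non_annotated`` is never stored; it is the complement of everything
    else and is produced only as a categorisation outcome.
    """

    features: list[Feature] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _by_id: dict[str, Feature] = field(default_factory=dict, repr=False)

    def add(self, feature: Feature) -> None:
        if feature.category not in CATEGORIES or feature.category == "non_annotated":
            raise FormatError(f"unknown feature category {feature.category!r}")
        if feature.start > feature.end:
            raise FormatError(f"feature {feature.feature_id}: start > end")
        self.features.append(feature)
        tree = self._trees.setdefault(feature.contig, IntervalTree())
        # store 0-based half-open internally
        tree.addi(feature.start - 1, feature.end, feature)
        self._by_id[feature.feature_id] = feature

    def __len__(self) -> int:
        return len(self.features)

    def get(self, feature_id: str) -> Feature:
        try:
            return self._by_id[feature_id]
        except KeyError:
            raise ConfigurationError(f"unknown feature id {feature_id!r}") from None

    def overlapping(self, contig: str, start0: int, end0: int) -> list[Feature]:
        """Features overlapping [start0, end0) by >= 1 nt."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start0, end0)),
                      key=lambda f: (f.start, f.end, f.feature_id))

    @classmethod
    def from_records(cls, records: Iterable[GffRecord]) -> "FeatureSet":
        fs = cls()
        for i, rec in enumerate(records):
            category = rec.attributes.get("category")
            if category is None:
                raise FormatError(f"record {i + 1} lacks a category attribute")
            fid = rec.attributes.get("ID", f"feature{i + 1}")
            fs.add(Feature(rec.seqid, rec.start, rec.end, rec.strand, category, fid))
        return fs


def load_features(path: str | Path) -> FeatureSet:
    """Load a GFF3 (.gff/.gff3) or BED6 (.bed) annotation into a FeatureSet."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        records = read_bed(path)
    else:
        records = read_gff3(path)
    return FeatureSet.from_records(records)


def categorize_read(hits: list[Hit], features: FeatureSet,
                    priority: tuple[str, ...] = CATEGORY_PRIORITY) -> str:
    """Single category for a mapped read, evaluated over ALL of its hits."""
    found: set[str] = set()
    for hit in hits:
        for feat in features.overlapping(hit.contig, hit.start, hit.end):
            found.add(feat.category)
    for category in priority:
        if category in found:
            return category
    return "non_annotated"


def category_table(category_counts: dict[str, Counter]):
    """Per-sample read counts and percentages per category (incl. non_annotated).

    ``category_counts``: {sample: Counter(category -> reads)}.  Percentages
    are of each sample's mapped reads and sum to 100 per sample.
    """
    import pandas as pd

    rows = []
    for sample, counts in sorted(category_counts.items()):
        total = sum(counts.values())
        for category in CATEGORIES:
            n = counts.get(category, 0)
            rows.append((sample, category, n, 100.0 * n / total if total else 0.0))
    return pd.DataFrame(rows, columns=["sample", "category", "reads", "percent"])


def reads_per_feature_by_strand(read_hits: Iterable[tuple[list[Hit], int]],
                                features: FeatureSet, feature_id: str,
                                ) -> tuple[int, int, int]:
    """Count reads overlapping one feature, split by strand.

    ``read_hits`` yields ``(hits, multiplicity)`` per distinct read.  A read
    counts once toward the feature if >= 1 hit overlaps it; its strand class
    is the majority strand (relative to the feature's plus strand) over its
    overlapping hits, ties resolved to sense.  Returns
    ``(sense, antisense, n_ties)``.
    """
    feat = features.get(feature_id)
    f_start0, f_end0 = feat.start - 1, feat.end
    sense = antisense = ties = 0
    for hits, mult in read_hits:
        plus = minus = 0
        for hit in hits:
            if hit.contig != feat.contig:
                continue
            if hit.start < f_end0 and hit.end > f_start0:
                if hit.strand == feat.strand:
                    plus += 1
                else:
                    minus += 1
        if plus == 0 and minus == 0:
            continue
        if plus == minus:
            ties += mult
        if plus >= minus:
            sense += mult
        else:
            antisense += mult
    return sense, antisense, ties
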