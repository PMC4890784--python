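"""Exact-match short-read alignment reporting *all* placements on both strands.

This reproduces the contract of a perfect-match Bowtie run ("-v 0 -a"):
a read is mapped wherever the reference contains it verbatim, on either
strand, and every such placement is reported.  No mismatches, no MAPQ, no
random assignment of multi-mappers — downstream code decides how to weight
multiple hits.

The index is a seed k-mer table with full-length verification.  A naive
O(n*m) scan (:func:`naive_scan`) is kept alongside as the independent oracle
for testing; it shares nothing with the indexed path beyond the Hit type.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .errors import ConfigurationError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Hit(NamedTuple):
    contig: str
    start: int      # 0-based offset on the contig plus strand
    strand: str     # '+' or '-'
    length: int

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.length


_STRAND_ORDER = {"+": 0, "-": 1}


def _sort_key(hit: Hit):
    return (hit.contig, hit.start, _STRAND_ORDER[hit.strand])


class ReferenceIndex:
    """Seed k-mer index over a set of contigs.

    k-mers containing non-ACGT bases are never indexed, so reads can only be
    placed over unambiguous reference sequence (a perfect match to N is
    impossible by definition).
    """

    def __init__(self, reference: dict[str, str], k: int = 12):
        if k < 4:
            raise ConfigurationError(f"seed length k={k} below minimum of 4")
        self.k = k
        self.contigs = {name: seq.upper() for name, seq in reference.items()}
        self.contig_lengths = {name: len(seq) for name, seq in self.contigs.items()}
        seeds: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(self.contigs):
            seq = self.contigs[name]
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if "N" in kmer:
                    continue
                seeds.setdefault(kmer, []).append((name, pos))
        self.seeds = seeds

    def n_seed_positions(self) -> int:
        return sum(len(v) for v in self.seeds.values())


def build_index(reference: dict[str, str], k: int = 12) -> ReferenceIndex:
    return ReferenceIndex(reference, k=k)


def _seed_hits(index: ReferenceIndex, query: str, strand: str) -> list[Hit]:
    k = index.k
    length = len(query)
    postings = index.seeds.get(query[:k])
    if not postings:
        return []
    hits = []
    contigs = index.contigs
    for contig, pos in postings:
        if contigs[contig][pos:pos + length] == query:
            hits.append(Hit(contig, pos, strand, length))
    return hits


def align_read(index: ReferenceIndex, read: str) -> list[Hit]:
    """All perfect-match placements of ``read`` (both strands), sorted
    (contig, start, '+' before '-')."""
    read = read.upper()
    if len(read) < index.k:
        raise ConfigurationError(
            f"read length {len(read)} below seed length k={index.k}")
    hits = _seed_hits(index, read, "+")
    rc = revcomp(read)
    # a minus-strand hit means revcomp(read) matches the plus strand there
    hits += _seed_hits(index, rc, "-")
    hits.sort(key=_sort_key)
    return hits


def naive_scan(reference: dict[str, str], read: str) -> list[Hit]:
    """Brute-force oracle: scan every contig with str.find on both strands."""
    read = read.upper()
    queries = ((read, "+"), (revcomp(read), "-"))
    hits = []
    for name in sorted(reference):
        seq = reference[name].upper()
        for query, strand in queries:
            start = seq.find(query)
            while start != -1:
                hits.append(Hit(name, start, strand, len(read)))
                start = seq.find(query, start + 1)
    hits.sort(key=_sort_key)
    return hits


@dataclass
class AlignmentSet:
    """Per-read hit lists plus the mapped/unmapped accounting."""

    hits: list[list[Hit]] = field(default_factory=list)
    mapped: int = 0
    unmapped: int = 0

    @property
    def total(self) -> int:
        return self.mapped + self.unmapped

    @property
    def mapped_fraction(self) -> float:
        return self.mapped / self.total if self.total else 0.0


def align_library(index: ReferenceIndex, reads: Iterable[str]) -> AlignmentSet:
    result = AlignmentSet()
    cache: dict[str, list[Hit]] = {}
    for read in reads:
        hits = cache.get(read)
        if hits is None:
            hits = align_read(index, read)
            cache[read] = hits
        result.hits.append(hits)
        if hits:
            result.mapped += 1
        else:
            result.unmapped += 1
    return result


def align_unique(index: ReferenceIndex, counts: Counter | dict[str, int],
                 cache: dict[str, list[Hit]] | None = None) -> dict[str, list[Hit]]:
    """Align each distinct sequence once; duplicated reads reuse the result.

    ``cache`` may be shared across libraries of one run so that a sequence
    seen in several samples is aligned a single time.
    """
    if cache is None:
        cache = {}
    out = {}
    for seq in counts:
        hits = cache.get(seq)
        if hits is None:
            hits = align_read(index, seq)
            cache[seq] = hits
        out[seq] = hits
    return out


def export_hits_table(reads: Iterable[str], alignment: AlignmentSet):
    """SAM-like TSV rows: read id index, contig, 1-based start, strand, length, n_hits."""
    import pandas as pd

    rows = []
    for i, (read, hits) in enumerate(zip(reads, alignment.hits)):
        for hit in hits:
            rows.append((i, read, hit.contig, hit.start + 1, hit.strand,
                         hit.length, len(hits)))
    return pd.DataFrame(rows, columns=["read_index", "sequence", "contig",
                                       "start", "strand", "length", "n_hits"])
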