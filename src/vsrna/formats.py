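"""Readers and writers for every on-disk format the pipeline touches.

Coordinate policy, stated once for the whole package: coordinates are
0-based half-open in memory and 1-based inclusive in every file we read or
write (FASTA indices, GFF3, report tables).  FASTA and FASTQ go through
Biopython; GFF3/BED/sample sheets are thin line parsers because the files
are plain 6/9-column tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

# --------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: upper-case sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) tuples; wraps malformed input with a record number."""
    try:
        with open(path) as fh:
            for n, rec in enumerate(FastqGeneralIterator(fh), start=1):
                yield rec
    except ValueError as exc:  # Biopython raises bare ValueError on bad FASTQ
        raise FormatError(f"malformed FASTQ record: {exc}", line=None) from exc


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write (id, seq, qual) records; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# --------------------------------------------------------------------------
# GFF3 / BED


class GffRecord(NamedTuple):
    seqid: str
    source: str
    type: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    score: str
    strand: str
    phase: str
    attributes: dict[str, str]


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in col9.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"attribute {chunk!r} lacks '='")
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | Path) -> list[GffRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"GFF3 record has {len(cols)} columns, expected 9", lineno)
            try:
                start, end = int(cols[3]), int(cols[4])
                attrs = _parse_attributes(cols[8])
            except ValueError as exc:
                raise FormatError(f"bad GFF3 record: {exc}", lineno) from exc
            if start < 1 or end < start:
                raise FormatError(f"bad GFF3 interval {start}..{end}", lineno)
            records.append(GffRecord(cols[0], cols[1], cols[2], start, end,
                                     cols[5], cols[6], cols[7], attrs))
    return records


def write_gff3(path: str | Path, records: Iterable[GffRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = ";".join(f"{k}={v}" for k, v in r.attributes.items())
            fh.write("\t".join([r.seqid, r.source, r.type, str(r.start), str(r.end),
                                r.score, r.strand, r.phase, attrs]) + "\n")


def read_bed(path: str | Path) -> list[GffRecord]:
    """Read BED6 (0-based half-open) into the same 1-based GffRecord container.

    BED name column is carried as the ``ID`` attribute and, when it contains a
    ``category:`` prefix (``category:id``), the category is split out.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"BED record has {len(cols)} columns, expected >=6", lineno)
            try:
                start0, end0 = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"bad BED coordinates: {exc}", lineno) from exc
            if start0 < 0 or end0 <= start0:
                raise FormatError(f"bad BED interval {start0}..{end0}", lineno)
            name = cols[3]
            attrs = {"ID": name}
            if ":" in name:
                category, ident = name.split(":", 1)
                attrs = {"ID": ident, "category": category}
            records.append(GffRecord(cols[0], "bed", "region", start0 + 1, end0,
                                     cols[4], cols[5], ".", attrs))
    return records


# --------------------------------------------------------------------------
# Sample sheets and generic tables

SAMPLE_SHEET_COLUMNS = ["sample", "barcode", "genotype", "replicate", "fraction"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"barcode": str, "sample": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    return sheet


def write_table(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


# --------------------------------------------------------------------------
# Run configuration and manifests


@dataclasses.dataclass
class RunConfig:
    """Stage parameters shared by the pipeline drivers.

    Defaults follow the small-RNA protocol this pipeline models: 3' adapter
    constant region CTGTAG, inserts kept at 18-30 nt, exact-match alignment
    seeded with 12-mers.
    """

    adapter: str = "CTGTAG"
    min_len: int = 18
    max_len: int = 30
    barcode_layout: str = "adapter_then_barcode"
    k: int = 12
    min_overlap: int = 20
    alpha: float = 0.05
    window_nt: int = 21
    rpm_denominator: str = "parsed"  # or "mapped"
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(path: str | Path, stage: str, config: RunConfig,
                   inputs: Iterable[str | Path] = (), outputs: Iterable[str | Path] = ()) -> None:
    """Machine-readable record of one stage execution (enables exact re-runs)."""
    manifest = {
        "stage": stage,
        "parameters": config.to_dict(),
        "inputs": {str(p): sha256_of(p) for p in inputs if Path(p).exists()},
        "outputs": {str(p): sha256_of(p) for p in outputs if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
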