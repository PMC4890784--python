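"""Demultiplexing and 3' adapter removal for multiplexed small-RNA reads.

A raw read is ``insert + adapter-constant-region + inline barcode + filler``
(or ``insert + barcode + adapter`` under the alternative layout).  Parsing is
sequence-only and exact: the leftmost occurrence of the adapter prefix splits
the read, the barcode is matched verbatim, inserts with any N or with length
outside [min_len, max_len] are discarded.  Every input read is assigned
exactly one fate, so fate counts always partition the input — the accounting
contract the ParseLog enforces.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ConfigurationError
from .formats import iter_fastq

FATES = ("assigned", "no_adapter", "unknown_barcode", "contains_N", "too_short")

#: fate for inserts outside [min_len, max_len]; lengths above max share this
#: bucket (the fate set is closed; see the methods note)
TOO_SHORT = "too_short"


def _check_barcodes(barcodes: dict[str, str]) -> int:
    """Validate the barcode->sample map; returns the common barcode length."""
    if not barcodes:
        raise ConfigurationError("barcode map is empty")
    lengths = {len(b) for b in barcodes}
    codes = sorted(barcodes)
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            if b.startswith(a) or a.startswith(b):
                raise ConfigurationError(
                    f"barcode collision: {a!r} is a prefix of {b!r}")
    if len(lengths) != 1:
        # prefix-freeness already guaranteed above; mixed lengths still
        # ambiguous for fixed-width extraction
        raise ConfigurationError(f"barcodes have mixed lengths {sorted(lengths)}")
    return lengths.pop()


def parse_read(sequence: str, adapter_prefix: str, barcodes: dict[str, str],
               min_len: int = 18, max_len: int = 30,
               layout: str = "adapter_then_barcode") -> tuple[str, str] | str:
    """Parse one raw read.

    Returns ``(sample, insert)`` on success, otherwise one fate string from
    :data:`FATES`.  Failure precedence: no_adapter -> unknown_barcode ->
    contains_N -> too_short.
    """
    if len(adapter_prefix) < 4:
        raise ConfigurationError(f"adapter prefix {adapter_prefix!r} shorter than 4 nt")
    bc_len = _check_barcodes(barcodes)
    sequence = sequence.upper()

    adapter_at = sequence.find(adapter_prefix)
    if layout == "adapter_then_barcode":
        if adapter_at == -1:
            return "no_adapter"
        insert = sequence[:adapter_at]
        bc_start = adapter_at + len(adapter_prefix)
    elif layout == "barcode_then_adapter":
        # barcode sits immediately 5' of the adapter; need room for it
        while adapter_at != -1 and adapter_at < bc_len:
            adapter_at = sequence.find(adapter_prefix, adapter_at + 1)
        if adapter_at == -1:
            return "no_adapter"
        insert = sequence[:adapter_at - bc_len]
        bc_start = adapter_at - bc_len
    else:
        raise ConfigurationError(f"unknown barcode layout {layout!r}")

    barcode = sequence[bc_start:bc_start + bc_len]
    sample = barcodes.get(barcode)
    if sample is None:
        return "unknown_barcode"
    if "N" in insert:
        return "contains_N"
    if not (min_len <= len(insert) <= max_len):
        return TOO_SHORT
    return sample, insert


@dataclass
class ParseLog:
    """Per-fate and per-sample read accounting for one demultiplexing run."""

    fates: Counter = field(default_factory=Counter)
    per_sample: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.fates.values())

    def assert_partition(self, n_input: int) -> None:
        if self.total != n_input:
            raise AssertionError(
                f"fate counts {self.total} do not partition {n_input} input reads")

    def to_frame(self):
        import pandas as pd
        rows = [("fate", fate, self.fates.get(fate, 0)) for fate in FATES]
        rows += [("sample", s, n) for s, n in sorted(self.per_sample.items())]
        return pd.DataFrame(rows, columns=["kind", "name", "reads"])


def demultiplex_run(fastq: str | Path | Iterable[tuple[str, str, str]],
                    barcodes: dict[str, str], adapter_prefix: str = "CTGTAG",
                    min_len: int = 18, max_len: int = 30,
                    layout: str = "adapter_then_barcode",
                    failures_path: str | Path | None = None,
                    ) -> tuple[dict[str, Counter], ParseLog]:
    """Demultiplex a multiplexed FASTQ into per-sample insert counters.

    Returns ``({sample: Counter(insert)}, ParseLog)``.  Read IDs are not
    keys: duplicate IDs are processed independently.  Rejected reads are
    optionally echoed to ``failures_path`` with their fate appended to the ID.
    """
    _check_barcodes(barcodes)
    records = iter_fastq(fastq) if isinstance(fastq, (str, Path)) else fastq
    per_sample: dict[str, Counter] = {s: Counter() for s in barcodes.values()}
    log = ParseLog()
    fail_fh = open(failures_path, "w") if failures_path else None
    try:
        for rid, seq, qual in records:
            outcome = parse_read(seq, adapter_prefix, barcodes,
                                 min_len=min_len, max_len=max_len, layout=layout)
            if isinstance(outcome, str):
                log.fates[outcome] += 1
                if fail_fh:
                    fail_fh.write(f"@{rid} {outcome}\n{seq}\n+\n{qual}\n")
            else:
                sample, insert = outcome
                log.fates["assigned"] += 1
                log.per_sample[sample] += 1
                per_sample[sample][insert] += 1
    finally:
        if fail_fh:
            fail_fh.close()
    return per_sample, log
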