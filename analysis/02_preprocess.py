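#!/usr/bin/env python
"""Demultiplex and adapter-trim the multiplexed small-RNA FASTQ.

Reports the per-fate accounting (assigned / no_adapter / unknown_barcode /
contains_N / too_short) and per-sample assigned totals; writes
results/parse_log.tsv.
"""

from common import WORKDIR, run_config, sim_config
from vsrna.pipeline import run_stage


def main() -> None:
    out = run_stage("preprocess", sim_config(), run_config(), WORKDIR)
    log = out["analysis"].parse_log
    print(f"{log.total:,} raw reads")
    for fate, count in sorted(log.fates.items()):
        print(f"  {fate:16s} {count:>10,}")
    print("per-sample assigned totals:")
    for sample, count in sorted(log.per_sample.items()):
        print(f"  {sample:16s} {count:>10,}")


if __name__ == "__main__":
    main()
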