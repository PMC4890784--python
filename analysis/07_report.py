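#!/usr/bin/env python
"""Consolidate every panel-equivalent table into results/.

Re-runs the in-memory analysis from the simulated files and writes one TSV
per table: parse log, category percentages, per-library viral statistics
with significance letters, size/5'-nt distributions, RNA-seq strand tables,
Tukey comparisons, and the virus layout.
"""

from common import RESULTS, WORKDIR, run_config, sim_config
from vsrna.discovery import annotate_virus
from vsrna.formats import read_fasta, write_table
from vsrna.pipeline import run_stage, report_tables
from vsrna.synthetic import VIRUS_CONTIG


def main() -> None:
    cfg, rc = sim_config(), run_config()
    analysis = run_stage("profile", cfg, rc, WORKDIR)["analysis"]
    import pandas as pd
    rnaseq = pd.read_csv(RESULTS / "rnaseq_viral.tsv", sep="\t")
    from vsrna.formats import read_sample_sheet
    sheet = read_sample_sheet(WORKDIR / "data" / "sample_sheet.tsv")
    virus = read_fasta(WORKDIR / "reference" / "virus.fasta")[VIRUS_CONTIG]
    tables = report_tables(analysis, rnaseq, sheet, annotate_virus(virus),
                           alpha=rc.alpha)
    for name, frame in tables.items():
        path = RESULTS / f"{name}.tsv"
        write_table(path, frame)
        print(f"wrote {path.relative_to(RESULTS.parent)} "
              f"({len(frame)} rows)")


if __name__ == "__main__":
    main()
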