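#!/usr/bin/env python
"""Simulate the study: reference genome + virus, annotations, multiplexed
small-RNA libraries, and strand-specific RNA-seq libraries.

Writes FASTA/GFF3/FASTQ plus sample sheet and truth tables under
scratch/pipeline/ for the downstream drivers.
"""

from common import WORKDIR, run_config, sim_config
from vsrna.pipeline import run_stage


def main() -> None:
    cfg = sim_config()
    out = run_stage("simulate", cfg, run_config(), WORKDIR)
    reference, run = out["reference"], out["srna"]
    n_samples = len(run.sample_sheet)
    print(f"reference: {len(reference.genome)} host contigs "
          f"({sum(map(len, reference.genome.values())):,} bp), "
          f"virus {len(reference.virus):,} nt, "
          f"{len(reference.features)} annotated features")
    print(f"small RNA: {n_samples} libraries x {cfg.reads_per_library:,} reads "
          f"-> {run.fastq_path}")
    print(f"RNA-seq:   {n_samples} libraries x "
          f"{cfg.rnaseq_reads_per_library:,} reads")
    viral = (run.truth["category"] == "viral").groupby(run.truth["sample"]).mean()
    print("true viral small-RNA fraction by library:")
    print(viral.to_string(float_format="%.4f"))


if __name__ == "__main__":
    main()
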