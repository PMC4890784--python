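"""Shared configuration for the numbered analysis drivers.

One seed, one study design, one working directory: the drivers are thin
narrative wrappers around ``vsrna.pipeline.run_stage`` and communicate only
through the files under WORKDIR, so any driver can be re-run in isolation
once its upstream stage has run.
"""

from pathlib import Path

from vsrna.formats import RunConfig
from vsrna.synthetic import SimConfig, default_genotypes

ROOT = Path(__file__).resolve().parent.parent
WORKDIR = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"

SEED = 20240906


def sim_config() -> SimConfig:
    """The default in-silico study: 8 genotypes x 2 replicates, 20k
    small-RNA and 20k RNA-seq reads per library (desk-scale)."""
    return SimConfig(seed=SEED, reads_per_library=20_000,
                     rnaseq_reads_per_library=20_000,
                     genotypes=default_genotypes(n_replicates=2))


def run_config() -> RunConfig:
    return RunConfig(seed=SEED, out_dir=str(RESULTS))
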