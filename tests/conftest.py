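"""Shared fixtures: one small synthetic experiment reused across test modules.

Two genotypes (a silencing-proficient control and a DCL-loss mutant) at a
few thousand reads per library keep every downstream stage exercised while
the full-scale designs live in the dedicated end-to-end tests.
"""

import numpy as np
import pytest

from vsrna.formats import RunConfig
from vsrna.pipeline import analyze_small_rna
from vsrna.synthetic import (GenotypeProfile, SimConfig, default_genotypes,
                             simulate_reference, simulate_rnaseq_run,
                             simulate_small_rna_run)


def two_genotype_config(seed: int = 11, reads: int = 4000) -> SimConfig:
    control, dcl1 = [g for g in default_genotypes(n_replicates=2)
                     if g.name in ("control", "dcl1")]
    return SimConfig(seed=seed, reads_per_library=reads,
                     rnaseq_reads_per_library=4000, genotypes=[control, dcl1])


@pytest.fixture(scope="session")
def base_cfg() -> SimConfig:
    return two_genotype_config()


@pytest.fixture(scope="session")
def reference(base_cfg):
    return simulate_reference(base_cfg)


@pytest.fixture(scope="session")
def srna_run(base_cfg, reference, tmp_path_factory):
    out = tmp_path_factory.mktemp("srna")
    return simulate_small_rna_run(base_cfg, reference, out)


@pytest.fixture(scope="session")
def rnaseq_run(base_cfg, reference, tmp_path_factory):
    out = tmp_path_factory.mktemp("rnaseq")
    return simulate_rnaseq_run(base_cfg, reference, out)


@pytest.fixture(scope="session")
def analysis(srna_run, reference):
    return analyze_small_rna(srna_run.fastq_path, srna_run.barcodes,
                             reference.expanded, reference.features,
                             RunConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
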