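#!/usr/bin/env python
"""Compute the viral small-RNA statistics per library: RPM, sense:antisense
ratio, size-by-strand and 5'-nucleotide distributions, and the
sRNA:RNA-seq ratio (normalised by each genotype's mean viral RNA-seq RPM).

Writes results/viral_srna_summary.tsv and results/rnaseq_viral.tsv.
"""

import pandas as pd

from common import WORKDIR, run_config, sim_config
from vsrna.pipeline import run_stage


def main() -> None:
    analysis = run_stage("profile", sim_config(), run_config(), WORKDIR)["analysis"]
    summary = analysis.summary_frame()
    pd.set_option("display.width", 160)
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    control = summary[summary["sample"].str.startswith("control")]
    print(f"\ncontrol means: sense:antisense "
          f"{control['ratio_sense_antisense'].mean():.2f}, "
          f"5'U {control['pct_5pU'].mean():.1f}%, "
          f"sRNA:RNA-seq {control['sr_to_rnaseq'].mean():.2f}")


if __name__ == "__main__":
    main()
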