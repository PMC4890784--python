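#!/usr/bin/env python
"""Align cleaned small RNAs (perfect matches, all hits) and assign each
mapped read a genomic category.

Writes results/mapping_summary.tsv and results/category_percentages.tsv —
the per-genotype summary of which loci produce small RNAs.
"""

from common import WORKDIR, run_config, sim_config
from vsrna.pipeline import run_stage


def main() -> None:
    cfg, rc = sim_config(), run_config()
    analysis = run_stage("align", cfg, rc, WORKDIR)["analysis"]
    for sample in sorted(analysis.mapped):
        total = analysis.mapped[sample] + analysis.unmapped[sample]
        print(f"{sample:16s} mapped {analysis.mapped[sample]:>8,} / {total:,} "
              f"({100 * analysis.mapped[sample] / total:.2f}%)")
    run_stage("categorize", cfg, rc, WORKDIR)
    table = analysis.category_frame()
    viral = table.query("category == 'viral'").set_index("sample")["percent"]
    print("viral share of mapped small RNAs (%):")
    print(viral.to_string(float_format="%.2f"))


if __name__ == "__main__":
    main()
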