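#!/usr/bin/env python
"""Recover the virus from unmapped RNA-seq reads and annotate its genome.

Aligns the DCL-loss RNA-seq libraries to the host-only reference, greedily
assembles the unmapped reads, ranks contigs by the fraction of unmapped
reads they absorb, and annotates the dominant contig: ORFs with frames,
UTRs, inter-ORF spacer, and -1 frameshift slippery-site candidates.
Writes results/contig_ranking.tsv.
"""

from common import WORKDIR, run_config, sim_config
from vsrna.pipeline import run_stage


def main() -> None:
    out = run_stage("discover", sim_config(), run_config(), WORKDIR)
    contigs, layout = out["contigs"], out["layout"]
    print(f"{len(out['unmapped']):,} unmapped RNA-seq reads -> "
          f"{len(contigs)} contigs")
    top = contigs[0]
    print(f"dominant contig: {len(top):,} nt, absorbs "
          f"{100 * top.assigned_fraction:.1f}% of unmapped reads")
    print(f"layout: 5'UTR {layout.five_prime_utr_nt} nt | "
          f"ORF1 {layout.orfs[0].start}-{layout.orfs[0].end} "
          f"(frame {layout.orfs[0].frame}, {layout.orfs[0].length_aa} aa) | "
          f"spacer {layout.spacer_nt} nt | "
          f"ORF2 {layout.orfs[1].start}-{layout.orfs[1].end} "
          f"(frame {layout.orfs[1].frame}, {layout.orfs[1].length_aa} aa) | "
          f"3'UTR {layout.three_prime_utr_nt} nt")
    for site in layout.slippery_sites:
        print(f"slippery candidate {site.sequence} at {site.position} "
              f"({site.distance_to_stop} nt from the ORF1 stop)")


if __name__ == "__main__":
    main()
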