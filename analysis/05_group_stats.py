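#!/usr/bin/env python
"""Compare scaled viral small-RNA abundance across genotypes: one-way ANOVA
with Tukey HSD post-hoc intervals (family-wise 95%).

Writes results/tukey_viral_rpm.tsv and prints the pairs whose adjusted p
falls below alpha.
"""

from common import WORKDIR, run_config, sim_config
from vsrna.pipeline import run_stage


def main() -> None:
    out = run_stage("stats", sim_config(), run_config(), WORKDIR)
    result, letters = out["tukey"], out["letters"]
    print(f"ANOVA: F = {result.anova_f:.2f}, p = {result.anova_p:.3g} "
          f"(df within = {result.df_within})")
    sig = result.significant_pairs()
    print(f"{len(sig)} / {len(result.pairs)} genotype pairs differ at "
          f"alpha = {result.alpha}:")
    for row in sig.itertuples():
        print(f"  {row.group1} vs {row.group2}: diff {row.difference:,.0f} RPM "
              f"[{row.lower:,.0f}, {row.upper:,.0f}], p_adj = {row.p_adj:.2g}")
    marked = [g for g, letter in letters.items() if letter]
    print(f"genotypes differing from control: {', '.join(marked) or 'none'}")


if __name__ == "__main__":
    main()
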