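#!/usr/bin/env python
"""Harmonize the two GC-corrected tables and prune SNPs in LD.

Pairwise r2 is computed from the simulated reference panel within 250 kb and
the paired SNP set clumped greedily at r2 > 0.2, ranking SNPs by
min(p1, p2).  Writes results/sim/pruned.tsv.
"""

import os

from pleioconj.ld import GenotypePanel, clump, compute_r2_window
from pleioconj.sumstats import (ColumnMap, harmonize_pair, read_sumstats,
                                write_table)

SIM = "results/sim"


CANONICAL = ColumnMap(variant_id="variant_id", chrom="chrom", pos="pos",
                      effect_allele="effect_allele", other_allele="other_allele",
                      p="p", z="z", n="n", intergenic="intergenic")


def main() -> None:
    s1 = read_sumstats(os.path.join(SIM, "trait1_gc.tsv"), CANONICAL,
                       trait="trait1")
    s2 = read_sumstats(os.path.join(SIM, "trait2_gc.tsv"), CANONICAL,
                       trait="trait2")
    paired = harmonize_pair(s1, s2)
    panel = GenotypePanel.from_tsv(os.path.join(SIM, "panel.tsv"))
    ld = compute_r2_window(panel, window_kb=250)
    pruned = clump(paired, ld, r2_threshold=0.2, window_kb=250, rank_p="min")
    write_table(pruned, os.path.join(SIM, "pruned.tsv"))
    print(f"harmonized {len(paired)} SNPs; retained {len(pruned)} after "
          f"clumping at r2>0.2 within 250 kb "
          f"({len(ld)} LD pairs from the panel)")


if __name__ == "__main__":
    main()
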