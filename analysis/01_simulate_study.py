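#!/usr/bin/env python
"""Simulate the synthetic paired-GWAS study used by the downstream analyses.

One replicate of 20,000 SNPs in 20-SNP AR(1) LD blocks (rho = 0.6), with
mixture (0.94, 0.025, 0.025, 0.01), mild inflation (lambda* = 1.1) on both
traits, toy gene annotation and a matching genotype panel.  Writes the two
trait tables, truth labels, gene BED and panel under results/sim/.
"""

import os

import pandas as pd

from pleioconj.simulate import (SimConfig, genes_to_bed, simulate_paired_gwas,
                                simulate_panel)

OUT = "results/sim"
CONFIG = SimConfig(m_snps=20_000, ld_block_size=20, ld_rho=0.6,
                   inflation=1.1, seed=20260922)


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    sim = simulate_paired_gwas(CONFIG)
    colnames = {"variant_id": "SNP", "chrom": "CHR", "pos": "BP",
                "effect_allele": "A1", "other_allele": "A2",
                "p": "P", "z": "Z", "n": "N", "intergenic": "INTERGENIC"}
    for name, st in (("trait1", sim.stats1), ("trait2", sim.stats2)):
        st.df.rename(columns=colnames).to_csv(
            os.path.join(OUT, f"{name}.tsv"), sep="\t", index=False,
            float_format="%.15e")
    sim.truth.to_csv(os.path.join(OUT, "truth.tsv"), sep="\t", index=False,
                     float_format="%.15e")
    genes_to_bed(sim.genes).to_csv(os.path.join(OUT, "genes.bed"), sep="\t",
                                   index=False, header=False)
    panel = simulate_panel(CONFIG, n_samples=200)
    pd.concat([panel.variants,
               pd.DataFrame(panel.dosages,
                            columns=[f"S{i}" for i in range(200)])],
              axis=1).to_csv(os.path.join(OUT, "panel.tsv"), sep="\t",
                             index=False)
    counts = sim.truth["label"].value_counts()
    print(f"simulated {CONFIG.m_snps} SNPs: "
          + ", ".join(f"{k}={counts.get(k, 0)}"
                      for k in ("null", "trait1", "trait2", "shared")))
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
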