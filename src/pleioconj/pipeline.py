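"""End-to-end driver: two summary-statistics tables in, loci and figures out.

Stage order follows the analysis design: genomic control per trait on
intergenic SNPs, allele harmonization into a paired table, LD clumping,
conditional QQ / fold-enrichment diagnostics, conditional and conjunctional
FDR, locus merging, closest-gene annotation, and Manhattan plots.  Each stage
is a thin call into the corresponding module so results are identical to
running the stages by hand.
"""

from __future__ import annotations

import logging
import os

import pandas as pd

from . import annotate, cfdr, enrichment, genomic_control, ld, sumstats

logger = logging.getLogger(__name__)


def run_pipeline(stats1: sumstats.SumStatsTable, stats2: sumstats.SumStatsTable,
                 genes: pd.DataFrame | None = None,
                 ld_table: ld.LDPairTable | None = None,
                 out_dir: str | None = None, *,
                 apply_gc: bool = True, deflate: bool = True,
                 drop_ambiguous: bool = True,
                 r2_threshold: float = 0.2, window_kb: float = 250.0,
                 rank_p: str = "min",
                 cutpoints: tuple = (0.0, 1.0, 2.0, 3.0),
                 conditional_threshold: float = cfdr.CONDITIONAL_FDR_THRESHOLD,
                 conjunctional_threshold: float = cfdr.CONJUNCTIONAL_FDR_THRESHOLD,
                 monotone: bool = True, merge_kb: float = 250.0,
                 exclude_region: tuple | None = None,
                 render: bool = True) -> dict:
    """Run every stage and (optionally) write tables and figures to ``out_dir``.

    Returns a dict with the intermediate and final artifacts: gc results,
    paired and pruned tables, enrichment curves, the cFDR record table,
    selections and annotated locus reports for both modes.
    """
    out: dict = {}

    if apply_gc:
        for slot, st in (("1", stats1), ("2", stats2)):
            gene_arg = None if "intergenic" in st.df.columns else genes
            gc = genomic_control.estimate_lambda(st, gene_arg)
            out[f"gc{slot}"] = gc
            corrected = genomic_control.apply_genomic_control(st, gc, deflate=deflate)
            if slot == "1":
                stats1 = corrected
            else:
                stats2 = corrected
            logger.info("trait %s lambda_GC = %.4f", slot, gc.lambda_gc)

    paired = sumstats.harmonize_pair(stats1, stats2, drop_ambiguous=drop_ambiguous)
    out["paired"] = paired

    if ld_table is not None and len(ld_table):
        pruned = ld.clump(paired, ld_table, r2_threshold, window_kb, rank_p)
    else:
        logger.warning("no LD information supplied; SNPs treated as unlinked")
        pruned = paired.copy()
    out["pruned"] = pruned

    spec = enrichment.StratumSpec(cutpoints=tuple(cutpoints))
    qq = enrichment.conditional_qq_curves(pruned, spec)
    folds = enrichment.fold_enrichment_curves(pruned, spec)
    out["qq_curves"] = qq
    out["fold_curves"] = folds

    records = cfdr.compute_cfdr(pruned, monotone=monotone)
    out["records"] = records

    for mode, thr in (("conditional", conditional_threshold),
                      ("conjunctional", conjunctional_threshold)):
        sel = cfdr.select_loci(records, mode, thr,
                               conditioning_trait=paired.trait2,
                               exclude_region=exclude_region)
        loci = annotate.merge_into_loci(sel, merge_kb)
        if genes is not None and len(loci):
            loci = annotate.assign_closest_gene(loci, genes)
        out[f"{mode}_calls"] = sel
        out[f"{mode}_loci"] = loci

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        sumstats.write_table(pruned, os.path.join(out_dir, "pruned.tsv"))
        sumstats.write_table(records, os.path.join(out_dir, "cfdr.tsv"))
        for mode in ("conditional", "conjunctional"):
            loci = out[f"{mode}_loci"]
            if len(loci):
                sumstats.write_table(loci, os.path.join(out_dir, f"{mode}_loci.tsv"))
            else:  # keep a header-only report so downstream globs find it
                loci.to_csv(os.path.join(out_dir, f"{mode}_loci.tsv"),
                            sep="\t", index=False)
        if render:
            enrichment.render_enrichment(qq, folds,
                                         os.path.join(out_dir, "enrichment"))
            for mode in ("conditional", "conjunctional"):
                annotate.manhattan_series(
                    records, mode,
                    conditional_threshold if mode == "conditional"
                    else conjunctional_threshold,
                    genes=genes, out_prefix=os.path.join(out_dir, mode))
    return out
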