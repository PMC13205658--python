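"""Differential H3K27me3 occupancy and intersection with upregulated genes.

Peak counts are simulated with 10% of peaks losing the repressive mark
(planted log2FC = -2) after knockdown; differential occupancy is called
at FDR < 0.1 and |log2FC| > 1, peaks are annotated to their nearest-TSS
gene, and the genes losing H3K27me3 are intersected with genes called
upregulated in a matched RNA experiment (FDR < 0.05, log2FC > 0.5) to
nominate direct targets of the repressive machinery.

Usage: python analysis/05_chip_integration.py [--seed 1] [--out results]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lncfunnel import expression as xp
from lncfunnel.chip import differential_occupancy, intersect_direct_targets
from lncfunnel.synthetic import gen_chip_counts, PlantedTruth
from lncfunnel.expression import CountMatrix


def matched_rna_experiment(chip_truth: PlantedTruth, gene_ids, seed: int):
    """RNA counts over the ChIP gene universe: genes whose promoter peak
    lost H3K27me3 are planted as upregulated (direct derepression),
    plus an equally sized independent set (indirect effects)."""
    rng = np.random.default_rng(seed + 7)
    derepressed = {f"cgene{pid[4:]}" for pid in chip_truth.diff_peak_ids}
    others = [g for g in gene_ids if g not in derepressed]
    indirect = set(rng.choice(others, size=len(derepressed), replace=False).tolist())
    up_truth = derepressed | indirect
    base = np.exp(rng.uniform(np.log(50), np.log(1000), size=len(gene_ids)))
    mu_a, mu_b = base.copy(), base.copy()
    up_idx = [i for i, g in enumerate(gene_ids) if g in up_truth]
    mu_b[up_idx] *= 2.0**1.5
    counts = np.column_stack(
        [rng.negative_binomial(20, 20 / (20 + mu)) for mu in (mu_a,) * 3 + (mu_b,) * 3]
    )
    samples = [f"ctl{j}" for j in range(3)] + [f"kd{j}" for j in range(3)]
    cm = CountMatrix(
        list(gene_ids), samples, counts,
        {s: ("control" if s.startswith("ctl") else "kd") for s in samples},
    )
    return cm, up_truth, derepressed


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    peaks, annot, group_of, chip_truth = gen_chip_counts(seed=args.seed)
    occ = differential_occupancy(
        peaks, group_of, list(group_of), "control", "kd", annot=annot
    )
    xp.results_to_frame(occ.results).to_csv(
        args.out / "chip_occupancy.tsv", sep="\t", index=False
    )
    print("differential H3K27me3 occupancy (FDR < 0.1, |log2FC| > 1)")
    print(f"  planted differential peaks: {len(chip_truth.diff_peak_ids)}")
    print(f"  decreased: {len(occ.decreased_peaks)} peaks -> "
          f"{len(occ.decreased_genes)} genes; increased: {len(occ.increased_peaks)}")

    gene_ids = [g.gene_id for g in annot]
    cm, up_truth, derepressed = matched_rna_experiment(chip_truth, gene_ids, args.seed)
    rna = xp.nb_wald_test(cm, "control", "kd")
    up_called = set(
        xp.filter_enriched(rna, {}, padj_max=0.05, log2fc_min=0.5, biotype=None)
    )
    report = intersect_direct_targets(up_called, occ.decreased_genes)
    pd.Series(sorted(report.intersection)).to_csv(
        args.out / "direct_targets.tsv", sep="\t", index=False, header=["gene_id"]
    )
    print("ChIP-RNA intersection")
    print(f"  upregulated genes called: {len(up_called)} "
          f"(planted {len(up_truth)})")
    print(f"  direct targets (up AND decreased H3K27me3): {len(report.intersection)} "
          f"(planted derepressed: {len(derepressed)})")


if __name__ == "__main__":
    main()
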