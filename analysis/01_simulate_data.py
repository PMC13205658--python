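"""Generate every synthetic dataset the downstream analyses consume.

Writes the cell-type-sorted count matrix with its tissue atlas, the two
toy genomes with planted lncRNA homolog pairs, an MEA raster pair
(control-like and knockdown-like), promoter sequences with planted TF
motifs, and the H3K27me3 peak-count table — all seeded, with the planted
ground truth saved alongside for inspection.

Usage: python analysis/01_simulate_data.py [--seed 1] [--out results/data]
"""

import argparse
import json
from pathlib import Path

from lncfunnel import synthetic
from lncfunnel.io_formats import write_bed, write_fasta

from _common import CONTROL_RASTER_SPEC, KD_RASTER_SPEC, SHARP_PFM, fixed_qpcr_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    cm, profile, truth_expr = synthetic.gen_expression_experiment(seed=args.seed)
    cm.to_tsv(out / "counts.tsv", out / "samples.tsv")
    print(f"counts: {len(cm.gene_ids)} genes x {len(cm.sample_ids)} samples, "
          f"{len(truth_expr.enriched_gene_ids)} planted neuron-enriched lncRNAs")

    annot_a, annot_b, seqs_a, seqs_b, truth_hom = synthetic.gen_homolog_genomes(
        seed=args.seed
    )
    write_bed(annot_a, out / "species_a.bed")
    write_bed(annot_b, out / "species_b.bed")
    write_fasta(seqs_a, out / "lnc_a.fa")
    write_fasta(seqs_b, out / "lnc_b.fa")
    print(f"genomes: {len(truth_hom.homolog_pairs)} planted syntenic homolog pairs")

    ctl = synthetic.gen_spike_raster(seed=args.seed, **CONTROL_RASTER_SPEC)
    kd = synthetic.gen_spike_raster(seed=args.seed + 1, **KD_RASTER_SPEC)
    ctl.to_csv(out / "raster_control.csv")
    kd.to_csv(out / "raster_kd.csv")
    print(f"rasters: control {ctl.total_spikes()} spikes, kd {kd.total_spikes()} spikes")

    proms, truth_motif = synthetic.gen_motif_promoters(
        SHARP_PFM, n_genes=500, frac_positive=0.6, seed=args.seed
    )
    write_fasta(proms, out / "promoters.fa")
    print(f"promoters: {len(truth_motif.motif_positive_ids)}/500 planted motif-positive")

    peaks, chip_annot, chip_groups, truth_chip = synthetic.gen_chip_counts(
        seed=args.seed
    )
    with open(out / "chip_counts.tsv", "w") as fh:
        fh.write("peak_id\tchrom\tstart\tend\t" + "\t".join(chip_groups) + "\n")
        for p in peaks:
            fh.write(
                f"{p.peak_id}\t{p.interval.chrom}\t{p.interval.start}\t"
                f"{p.interval.end}\t" + "\t".join(map(str, p.counts)) + "\n"
            )
    write_bed(chip_annot, out / "chip_genes.bed")
    print(f"chip: {len(peaks)} peaks, {len(truth_chip.diff_peak_ids)} planted differential")

    fixed_qpcr_table().to_csv(out / "qpcr.tsv", sep="\t", index=False)

    truth = {
        "enriched": sorted(truth_expr.enriched_gene_ids),
        "brain_specific": sorted(truth_expr.brain_specific_ids),
        "homolog_pairs": sorted(map(list, truth_hom.homolog_pairs)),
        "motif_positive": sorted(truth_motif.motif_positive_ids),
        "diff_peaks": sorted(truth_chip.diff_peak_ids),
    }
    (out / "planted_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(f"wrote fixtures + planted truth under {out}/")


if __name__ == "__main__":
    main()
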