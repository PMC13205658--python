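"""Differential H3K27me3 occupancy and ChIP-RNA integration.

Starts from peak count tables (peak calling is upstream of this
package).  Peaks are assigned to the gene with the nearest TSS;
differential occupancy reuses the NB Wald test on the peak-count
matrix with the FDR < 0.1 and |log2FC| > 1 thresholds (strict), and
gene-level increased/decreased sets use an any-peak rule.  The direct-
target report is the exact intersection of upregulated genes with
genes losing the repressive mark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .expression import CountMatrix, DiffResult, nb_wald_test
from .io_formats import GeneAnnotation, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "DirectTargetReport",
    "OccupancyResult",
    "annotate_peaks",
    "differential_occupancy",
    "intersect_direct_targets",
]


@dataclass(frozen=True)
class Peak:
    """A called peak (strandless interval) with per-sample counts."""

    peak_id: str
    interval: GenomicInterval
    counts: tuple[int, ...]


@dataclass
class DirectTargetReport:
    up_genes: set[str]
    decreased_me3_genes: set[str]
    intersection: set[str]


@dataclass
class OccupancyResult:
    results: list[DiffResult]
    increased_peaks: set[str]
    decreased_peaks: set[str]
    increased_genes: set[str]
    decreased_genes: set[str]


def annotate_peaks(
    peaks: Sequence[Peak],
    annot: Sequence[GeneAnnotation],
    promoter_upstream: int = 1000,
) -> dict[str, tuple[str, str]]:
    """Assign each peak to the gene with the TSS nearest its midpoint.

    Feature is ``promoter`` when the midpoint lies in the strand-aware
    upstream window before the TSS, ``gene_body`` when inside the gene
    interval, else ``intergenic``.  TSS-distance ties break to the
    lexicographically smaller gene_id.
    """
    if not annot:
        raise ValueError("annotation must be non-empty")
    genes = sorted(annot, key=lambda g: g.gene_id)
    out: dict[str, tuple[str, str]] = {}
    for peak in peaks:
        mid = peak.interval.midpoint
        best = min(
            genes,
            key=lambda g: (
                (g.interval.chrom != peak.interval.chrom),
                abs(g.tss - mid),
                g.gene_id,
            ),
        )
        tss = best.tss
        if best.interval.strand == "+":
            in_promoter = tss - promoter_upstream <= mid < tss
        else:
            in_promoter = tss < mid <= tss + promoter_upstream
        if best.interval.chrom != peak.interval.chrom:
            feature = "intergenic"
        elif in_promoter:
            feature = "promoter"
        elif best.interval.start <= mid < best.interval.end:
            feature = "gene_body"
        else:
            feature = "intergenic"
        out[peak.peak_id] = (best.gene_id, feature)
    return out


def differential_occupancy(
    peaks: Sequence[Peak],
    group_of: Mapping[str, str],
    sample_ids: Sequence[str],
    group_a: str,
    group_b: str,
    annot: Sequence[GeneAnnotation] | None = None,
    fdr_max: float = 0.1,
    abs_log2fc_min: float = 1.0,
    promoter_upstream: int = 1000,
) -> OccupancyResult:
    """NB Wald differential occupancy on peak counts (group B vs A).

    Decreased peaks have padj < fdr_max AND log2FC < -abs_log2fc_min
    (strict); increased symmetrically.  When an annotation is supplied,
    a gene is increased/decreased if at least one assigned peak is.
    """
    cm = CountMatrix(
        gene_ids=[p.peak_id for p in peaks],
        sample_ids=list(sample_ids),
        counts=[list(p.counts) for p in peaks],
        group_of=dict(group_of),
    )
    results = nb_wald_test(cm, group_a, group_b)
    decreased = {
        r.gene_id for r in results if r.padj < fdr_max and r.log2fc < -abs_log2fc_min
    }
    increased = {
        r.gene_id for r in results if r.padj < fdr_max and r.log2fc > abs_log2fc_min
    }
    inc_genes: set[str] = set()
    dec_genes: set[str] = set()
    if annot is not None:
        assignment = annotate_peaks(peaks, annot, promoter_upstream)
        for peak_id, (gene_id, _feature) in assignment.items():
            if peak_id in increased:
                inc_genes.add(gene_id)
            if peak_id in decreased:
                dec_genes.add(gene_id)
    return OccupancyResult(results, increased, decreased, inc_genes, dec_genes)


def intersect_direct_targets(
    up_genes: set[str], decreased_me3_genes: set[str]
) -> DirectTargetReport:
    """Genes both upregulated and losing H3K27me3 — candidate direct targets."""
    inter = set(up_genes) & set(decreased_me3_genes)
    logger.info(
        "direct-target intersection: %d up, %d decreased, %d shared",
        len(up_genes),
        len(decreased_me3_genes),
        len(inter),
    )
    return DirectTargetReport(set(up_genes), set(decreased_me3_genes), inter)
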