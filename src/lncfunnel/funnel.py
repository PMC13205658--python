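"""The lncRNA discovery funnel.

Three nested filters over a cell-type-sorted expression experiment:

1. neuron-enrichment — lncRNAs with padj < 0.05 and log2FC > 3 in
   NeuN+ vs NeuN- differential expression;
2. cross-species conservation — survivors with a syntenic homolog at
   >= 40% sequence similarity;
3. brain specificity — survivors whose tissue-atlas profile is
   brain-enriched (tau >= 0.8 with a brain tissue on top).

Candidates are ranked by tau, then log2FC, encoding "highest
enrichment in the brain" as the final pick.  Every stage only removes
genes, so the report's stage lists are nested by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import expression as xp
from . import homology as hm
from .synthetic import GROUP_NEUN_NEG, GROUP_NEUN_POS, FunnelDataset

logger = logging.getLogger(__name__)

__all__ = ["FunnelConfig", "FunnelReport", "run_funnel"]


@dataclass
class FunnelConfig:
    """Thresholds of the discovery funnel (all strict except similarity)."""

    padj_max: float = 0.05
    log2fc_min: float = 3.0
    similarity_min: float = 0.40
    tau_min: float = 0.8
    group_a: str = GROUP_NEUN_NEG
    group_b: str = GROUP_NEUN_POS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.padj_max <= 1.0):
            raise ValueError("padj_max must lie in [0, 1]")
        if not (0.0 <= self.similarity_min <= 1.0):
            raise ValueError("similarity_min must lie in [0, 1]")
        if not (0.0 <= self.tau_min <= 1.0):
            raise ValueError("tau_min must lie in [0, 1]")


@dataclass
class FunnelReport:
    """Stage-by-stage survivors and the final ranked candidate list."""

    enriched: list[str]
    homologous: list[str]
    brain_filtered: list[str]
    ranked_candidates: list[str]
    stage_counts: dict[str, int] = field(default_factory=dict)
    homolog_calls: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def run_funnel(data: FunnelDataset, config: FunnelConfig | None = None) -> FunnelReport:
    """Run the three-stage funnel on one dataset.

    Deterministic given the inputs; per-stage survivor counts are
    logged and returned.  Any stage failing raises with the stage name.
    """
    config = config or FunnelConfig()
    try:
        results = xp.nb_wald_test(data.counts, config.group_a, config.group_b)
        enriched = sorted(
            xp.filter_enriched(
                results,
                data.counts.biotype_of,
                padj_max=config.padj_max,
                log2fc_min=config.log2fc_min,
                biotype="lncRNA",
            )
        )
    except Exception as exc:
        raise RuntimeError(f"funnel stage 'enrichment' failed: {exc}") from exc

    try:
        enriched_set = set(enriched)
        annot_survivors = [
            a
            for a in data.annot_a
            if a.biotype != "lncRNA" or a.gene_id in enriched_set
        ]
        calls = hm.call_homologs(
            annot_survivors,
            data.seqs_a,
            data.annot_b,
            data.seqs_b,
            similarity_min=config.similarity_min,
        )
        homologous = sorted(c.query_id for c in calls if c.is_homolog)
    except Exception as exc:
        raise RuntimeError(f"funnel stage 'homology' failed: {exc}") from exc

    try:
        tau = xp.tau_specificity(data.profile, tau_min=config.tau_min)
        brain_ok = set(tau.index[tau["brain_enriched"]])
        brain_filtered = sorted(g for g in homologous if g in brain_ok)
    except Exception as exc:
        raise RuntimeError(f"funnel stage 'tissue' failed: {exc}") from exc

    log2fc_of = {r.gene_id: r.log2fc for r in results}
    ranked = sorted(
        brain_filtered,
        key=lambda g: (-tau.loc[g, "tau"], -log2fc_of.get(g, 0.0), g),
    )
    report = FunnelReport(
        enriched=enriched,
        homologous=homologous,
        brain_filtered=brain_filtered,
        ranked_candidates=ranked,
        stage_counts={
            "enriched": len(enriched),
            "homologous": len(homologous),
            "brain_filtered": len(brain_filtered),
        },
        homolog_calls={c.query_id: c.similarity for c in calls},
    )
    logger.info("funnel stage counts: %s", report.stage_counts)
    return report
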