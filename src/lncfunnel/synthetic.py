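"""Seeded synthetic-data generators with planted ground truth.

Each generator is a pure function of its arguments (including the seed)
and emulates the statistical structure one analysis stage assumes:

* ``gen_expression_experiment`` — NB-distributed neuronal vs
  non-neuronal count matrices with planted enriched lncRNAs, plus a
  tissue atlas with planted brain-specific genes.  Counts follow
  var = mu + alpha * mu^2 with a single dispersion alpha; baseline
  means are log-uniform.
* ``gen_homolog_genomes`` — two toy genomes whose protein-coding
  scaffolds carry ortholog links; planted lncRNA homolog pairs are
  point-mutated copies at a controlled identity placed in syntenic
  loci, decoys are equally mutated copies placed between scaffold genes
  without ortholog links.
* ``gen_spike_raster`` — Poisson background spiking with optional
  exactly-constructed bursts, network bursts and a tunable synchrony
  level (shared-template spikes).
* ``gen_motif_promoters`` — uniform-composition promoters with the
  motif consensus embedded in a chosen fraction, either strand.
* ``gen_chip_counts`` — NB peak-count tables with planted differential
  occupancy, each peak lying in a generated gene promoter.
* ``gen_funnel_dataset`` — a coherent composite in which exactly one
  gene is simultaneously enriched, conserved and brain-specific.

Planted structures satisfy the corresponding detector's definition by
construction, so the detectors double as ground-truth checks in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chip import Peak
from .expression import CountMatrix, TissueProfile
from .io_formats import GeneAnnotation, GenomicInterval, PFMRecord, revcomp
from .mea import SpikeRaster

__all__ = [
    "PlantedTruth",
    "Peak",
    "gen_expression_experiment",
    "gen_homolog_genomes",
    "gen_spike_raster",
    "gen_motif_promoters",
    "gen_chip_counts",
    "gen_funnel_dataset",
    "FunnelDataset",
]

TISSUES = [
    "brain_cortex",
    "brain_cerebellum",
    "heart",
    "liver",
    "lung",
    "kidney",
    "muscle",
    "skin",
]
BRAIN_TISSUES = frozenset({"brain_cortex", "brain_cerebellum"})

GROUP_NEUN_NEG = "neun_neg"
GROUP_NEUN_POS = "neun_pos"


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators."""

    enriched_gene_ids: set[str] = field(default_factory=set)
    homolog_pairs: set[tuple[str, str]] = field(default_factory=set)
    brain_specific_ids: set[str] = field(default_factory=set)
    motif_positive_ids: set[str] = field(default_factory=set)
    motif_offsets: dict[str, tuple[int, str]] = field(default_factory=dict)
    diff_peak_ids: set[str] = field(default_factory=set)
    funnel_winner_id: str | None = None


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB counts with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _nb_count_matrix(
    rng: np.random.Generator,
    mu_a: np.ndarray,
    mu_b: np.ndarray,
    n_per_group: int,
    dispersion: float,
) -> np.ndarray:
    cols = [_nb_draw(rng, mu_a, dispersion) for _ in range(n_per_group)]
    cols += [_nb_draw(rng, mu_b, dispersion) for _ in range(n_per_group)]
    return np.column_stack(cols)


def _tissue_profile(
    rng: np.random.Generator,
    gene_ids: list[str],
    base_mean: np.ndarray,
    brain_specific: set[str],
) -> TissueProfile:
    """Atlas expression: broad genes have mildly noisy expression in every
    tissue; brain-specific genes are expressed only in brain tissues."""
    n_genes, n_tissues = len(gene_ids), len(TISSUES)
    noise = rng.lognormal(mean=0.0, sigma=0.2, size=(n_genes, n_tissues))
    expr = base_mean[:, None] * noise
    brain_cols = np.array([t in BRAIN_TISSUES for t in TISSUES])
    for i, g in enumerate(gene_ids):
        if g in brain_specific:
            expr[i, ~brain_cols] = 0.0
    return TissueProfile(gene_ids, list(TISSUES), expr, BRAIN_TISSUES)


def gen_expression_experiment(
    n_genes: int = 2000,
    n_per_group: int = 3,
    frac_enriched: float = 0.05,
    planted_log2fc: float = 4.0,
    dispersion: float = 0.05,
    mean_range: tuple[float, float] = (20.0, 2000.0),
    seed: int = 0,
    frac_lncrna: float = 0.3,
    frac_brain_specific: float = 0.05,
) -> tuple[CountMatrix, TissueProfile, PlantedTruth]:
    """Neuronal (NeuN+) vs non-neuronal (NeuN-) counts with planted
    neuron-enriched lncRNAs, plus a matching tissue atlas.

    Planted genes are lncRNAs whose NeuN+ group mean is
    2**planted_log2fc times the NeuN- mean; brain-specific atlas genes
    are a random subset of all genes.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if not (0.0 <= frac_enriched <= 1.0):
        raise ValueError("frac_enriched must lie in [0, 1]")
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    lo, hi = mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))

    n_lnc = int(round(frac_lncrna * n_genes))
    lnc_idx = rng.choice(n_genes, size=n_lnc, replace=False)
    biotype_of = {g: "protein_coding" for g in gene_ids}
    for i in lnc_idx:
        biotype_of[gene_ids[i]] = "lncRNA"

    n_planted = int(round(frac_enriched * n_genes))
    if n_planted > n_lnc:
        raise ValueError("frac_enriched exceeds the lncRNA fraction")
    planted_idx = rng.choice(lnc_idx, size=n_planted, replace=False)
    enriched = {gene_ids[i] for i in planted_idx}

    mu_neg = base.copy()
    mu_pos = base.copy()
    mu_pos[planted_idx] *= 2.0**planted_log2fc

    counts = _nb_count_matrix(rng, mu_neg, mu_pos, n_per_group, dispersion)
    sample_ids = [f"neg{j}" for j in range(n_per_group)] + [
        f"pos{j}" for j in range(n_per_group)
    ]
    group_of = {s: (GROUP_NEUN_NEG if s.startswith("neg") else GROUP_NEUN_POS)
                for s in sample_ids}
    cm = CountMatrix(gene_ids, sample_ids, counts, group_of, biotype_of)

    n_brain = int(round(frac_brain_specific * n_genes))
    brain_idx = rng.choice(n_genes, size=n_brain, replace=False)
    brain_specific = {gene_ids[i] for i in brain_idx}
    profile = _tissue_profile(rng, gene_ids, base, brain_specific)

    truth = PlantedTruth(
        enriched_gene_ids=enriched, brain_specific_ids=brain_specific
    )
    return cm, profile, truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate_to_identity(
    rng: np.random.Generator, seq: str, target_identity: float
) -> str:
    """Point-mutate exactly round((1 - t) * L) positions to different bases."""
    n_mut = int(round((1.0 - target_identity) * len(seq)))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


def gen_homolog_genomes(
    n_lnc: int = 12,
    n_scaffold_genes: int = 13,
    target_identity: float = 0.75,
    frac_syntenic: float = 0.5,
    seed: int = 0,
    lnc_len: int = 300,
) -> tuple[
    list[GeneAnnotation],
    list[GeneAnnotation],
    dict[str, str],
    dict[str, str],
    PlantedTruth,
]:
    """Two toy genomes with planted syntenic lncRNA homolog pairs.

    Species A carries ``n_scaffold_genes`` protein-coding genes with
    ortholog links into species B and one lncRNA between each pair of
    consecutive scaffold genes (up to ``n_lnc``).  A fraction
    ``frac_syntenic`` of them get a species-B homolog in the syntenic
    locus, mutated to ``target_identity``; the rest get an equally
    mutated decoy placed between unlinked species-B scaffold genes, so
    synteny alone separates the two classes.
    """
    if n_scaffold_genes < 2:
        raise ValueError("need at least 2 scaffold genes for flanks")
    if n_lnc > n_scaffold_genes - 1:
        raise ValueError("need n_scaffold_genes >= n_lnc + 1")
    if not (0.0 <= target_identity <= 1.0):
        raise ValueError("target_identity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    spacing = 10_000

    annot_a: list[GeneAnnotation] = []
    annot_b: list[GeneAnnotation] = []
    seqs_a: dict[str, str] = {}
    seqs_b: dict[str, str] = {}

    for i in range(n_scaffold_genes):
        base = i * spacing
        annot_a.append(
            GeneAnnotation(
                f"pcA_{i:03d}",
                GenomicInterval("chrA1", base + 1000, base + 3000, "+"),
                "protein_coding",
                ortholog_id=f"pcB_{i:03d}",
            )
        )
        annot_b.append(
            GeneAnnotation(
                f"pcB_{i:03d}",
                GenomicInterval("chrB1", base + 1000, base + 3000, "+"),
                "protein_coding",
            )
        )

    n_syn = int(round(frac_syntenic * n_lnc))
    syn_indices = set(rng.choice(n_lnc, size=n_syn, replace=False).tolist())

    # unlinked species-B scaffold for the decoys, downstream of the block
    n_decoy = n_lnc - n_syn
    decoy_base = (n_scaffold_genes + 2) * spacing
    for m in range(n_decoy + 1):
        base = decoy_base + m * spacing
        annot_b.append(
            GeneAnnotation(
                f"pcBx_{m:03d}",
                GenomicInterval("chrB1", base + 1000, base + 3000, "+"),
                "protein_coding",
            )
        )

    truth = PlantedTruth()
    decoy_slot = 0
    for j in range(n_lnc):
        base = j * spacing
        a_id, b_id = f"lncA_{j:03d}", f"lncB_{j:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        annot_a.append(
            GeneAnnotation(
                a_id,
                GenomicInterval("chrA1", base + 5000, base + 5000 + lnc_len, strand),
                "lncRNA",
            )
        )
        seq_a = _random_seq(rng, lnc_len)
        seqs_a[a_id] = seq_a
        seq_b = _mutate_to_identity(rng, seq_a, target_identity)
        if rng.random() < 0.5:  # annotation strand across species is unreliable
            seq_b = revcomp(seq_b)
        if j in syn_indices:
            b_base = base + 5000
            truth.homolog_pairs.add((a_id, b_id))
        else:
            b_base = decoy_base + decoy_slot * spacing + 5000
            decoy_slot += 1
        annot_b.append(
            GeneAnnotation(
                b_id,
                GenomicInterval("chrB1", b_base, b_base + lnc_len, strand),
                "lncRNA",
            )
        )
        seqs_b[b_id] = seq_b
    return annot_a, annot_b, seqs_a, seqs_b, truth


def _poisson_train(
    rng: np.random.Generator, rate: float, duration: float
) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def gen_spike_raster(
    n_electrodes: int = 16,
    duration: float = 900.0,
    base_rate: float = 1.0,
    burst_spec: tuple[int, int, float] | None = None,
    network_spec: tuple[int, int, int] | None = None,
    sync_level: float = 0.0,
    seed: int = 0,
) -> SpikeRaster:
    """Poisson-background raster with optional exact planted structure.

    burst_spec = (bursts per electrode, spikes per burst, intra-burst
    ISI seconds): runs written as literal spike times so each satisfies
    the burst definition.  network_spec = (n network bursts,
    participating electrodes, total spikes per event): pooled clusters
    with 2 ms pooled ISIs spread round-robin over the participants.
    sync_level s in [0, 1]: each electrode keeps a template spike with
    probability s and adds independent Poisson spikes at rate
    (1 - s) * base_rate, so s = 1 duplicates one template everywhere.
    Spikes falling outside [0, duration] are clipped.
    """
    if base_rate < 0 or duration <= 0:
        raise ValueError("rates and duration must be nonnegative/positive")
    if not (0.0 <= sync_level <= 1.0):
        raise ValueError("sync_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    electrode_ids = [f"E{i:02d}" for i in range(n_electrodes)]
    per_electrode: dict[str, list[np.ndarray]] = {e: [] for e in electrode_ids}

    template = (
        _poisson_train(rng, base_rate, duration) if sync_level > 0 else np.empty(0)
    )
    for e in electrode_ids:
        if sync_level > 0:
            keep = rng.random(template.size) < sync_level if sync_level < 1 else np.ones(
                template.size, dtype=bool
            )
            per_electrode[e].append(template[keep])
        indep_rate = base_rate * (1.0 - sync_level)
        if indep_rate > 0:
            per_electrode[e].append(_poisson_train(rng, indep_rate, duration))

    if burst_spec is not None:
        n_bursts, spikes_per_burst, intra_isi = burst_spec
        burst_len = (spikes_per_burst - 1) * intra_isi
        for e in electrode_ids:
            for k in range(n_bursts):
                slot = duration / max(n_bursts, 1)
                start = k * slot + 0.25 * slot + rng.uniform(0, 0.1 * slot)
                times = start + np.arange(spikes_per_burst) * intra_isi
                per_electrode[e].append(times)
        del burst_len

    if network_spec is not None:
        n_events, n_participating, spikes_total = network_spec
        if n_participating > n_electrodes:
            raise ValueError("participating electrodes exceed electrode count")
        pooled_isi = 0.002
        for k in range(n_events):
            center = (k + 0.5) * duration / n_events
            times = center + np.arange(spikes_total) * pooled_isi
            for idx, t in enumerate(times):
                e = electrode_ids[idx % n_participating]
                per_electrode[e].append(np.array([t]))

    spikes: dict[str, np.ndarray] = {}
    n_clipped = 0
    for e in electrode_ids:
        t = (
            np.concatenate(per_electrode[e])
            if per_electrode[e]
            else np.empty(0)
        )
        inside = (t >= 0) & (t <= duration)
        n_clipped += int((~inside).sum())
        spikes[e] = np.unique(t[inside])
    if n_clipped:
        import logging

        logging.getLogger(__name__).warning(
            "clipped %d spike(s) outside [0, duration]", n_clipped
        )
    return SpikeRaster(electrode_ids, spikes, duration)


def gen_motif_promoters(
    pfm: PFMRecord,
    n_genes: int = 500,
    frac_positive: float = 0.5,
    promoter_len: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, str], PlantedTruth]:
    """Uniform-composition promoters with the motif consensus embedded
    (either strand, recorded offset) in a ``frac_positive`` subset."""
    if not (0.0 <= frac_positive <= 1.0):
        raise ValueError("frac_positive must lie in [0, 1]")
    L = len(pfm)
    if promoter_len < L:
        raise ValueError("promoter_len must be >= motif length")
    rng = np.random.default_rng(seed)
    consensus = pfm.consensus
    gene_ids = [f"prom{i:04d}" for i in range(n_genes)]
    n_pos = int(round(frac_positive * n_genes))
    positive = set(rng.choice(gene_ids, size=n_pos, replace=False).tolist())
    seqs: dict[str, str] = {}
    truth = PlantedTruth(motif_positive_ids=positive)
    for g in gene_ids:
        seq = _random_seq(rng, promoter_len)
        if g in positive:
            offset = int(rng.integers(0, promoter_len - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            insert = consensus if strand == "+" else revcomp(consensus)
            seq = seq[:offset] + insert + seq[offset + L :]
            truth.motif_offsets[g] = (offset, strand)
        seqs[g] = seq
    return seqs, truth


def gen_chip_counts(
    n_peaks: int = 1000,
    n_per_group: int = 3,
    frac_diff: float = 0.1,
    planted_log2fc: float = -2.0,
    seed: int = 0,
    dispersion: float = 0.05,
    mean_range: tuple[float, float] = (20.0, 2000.0),
) -> tuple[list[Peak], list[GeneAnnotation], dict[str, str], PlantedTruth]:
    """NB peak-count table with planted differential occupancy.

    One gene is generated per peak and the peak placed inside that
    gene's promoter window, so peak-to-gene annotation and the
    downstream ChIP-RNA intersection are testable.  Returns
    (peaks, gene annotation, sample->group mapping, truth).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if not (0.0 <= frac_diff <= 1.0):
        raise ValueError("frac_diff must lie in [0, 1]")
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_peaks))
    n_planted = int(round(frac_diff * n_peaks))
    planted_idx = rng.choice(n_peaks, size=n_planted, replace=False)
    mu_a = base.copy()
    mu_b = base.copy()
    mu_b[planted_idx] *= 2.0**planted_log2fc
    counts = _nb_count_matrix(rng, mu_a, mu_b, n_per_group, dispersion)

    spacing = 5000
    peaks: list[Peak] = []
    annot: list[GeneAnnotation] = []
    for i in range(n_peaks):
        base_pos = i * spacing
        gene = GeneAnnotation(
            f"cgene{i:04d}",
            GenomicInterval("chrC1", base_pos + 2000, base_pos + 3000, "+"),
            "protein_coding",
        )
        annot.append(gene)
        # promoter of a + gene is [tss - upstream, tss); put the peak there
        peaks.append(
            Peak(
                f"peak{i:04d}",
                GenomicInterval("chrC1", base_pos + 1400, base_pos + 1800, "+"),
                tuple(int(c) for c in counts[i]),
            )
        )
    sample_ids = [f"ctl{j}" for j in range(n_per_group)] + [
        f"kd{j}" for j in range(n_per_group)
    ]
    group_of = {s: ("control" if s.startswith("ctl") else "kd") for s in sample_ids}
    truth = PlantedTruth(diff_peak_ids={f"peak{i:04d}" for i in planted_idx})
    return peaks, annot, group_of, truth


@dataclass
class FunnelDataset:
    """Everything the discovery funnel consumes, with planted truth."""

    counts: CountMatrix
    profile: TissueProfile
    annot_a: list[GeneAnnotation]
    annot_b: list[GeneAnnotation]
    seqs_a: dict[str, str]
    seqs_b: dict[str, str]
    truth: PlantedTruth


def gen_funnel_dataset(
    seed: int = 0,
    n_lnc: int = 12,
    n_per_group: int = 3,
    planted_log2fc: float = 4.0,
    dispersion: float = 0.05,
    target_identity: float = 0.75,
) -> FunnelDataset:
    """A coherent dataset in which exactly one lncRNA passes all three
    funnel stages (neuron-enriched, conserved, brain-specific).

    Half the lncRNAs are syntenically conserved.  Three are planted as
    neuron-enriched: the winner (conserved), one other conserved lncRNA
    that is not brain-specific, and one non-conserved lncRNA.  The
    brain-specific atlas genes are the winner, one non-enriched
    conserved lncRNA and one protein-coding gene.
    """
    rng = np.random.default_rng(seed)
    annot_a, annot_b, seqs_a, seqs_b, homolog_truth = gen_homolog_genomes(
        n_lnc=n_lnc,
        n_scaffold_genes=n_lnc + 1,
        target_identity=target_identity,
        frac_syntenic=0.5,
        seed=int(rng.integers(2**31)),
    )
    syntenic = sorted(a for a, _ in homolog_truth.homolog_pairs)
    non_syntenic = sorted(
        a.gene_id
        for a in annot_a
        if a.biotype == "lncRNA" and a.gene_id not in syntenic
    )
    if len(syntenic) < 3 or len(non_syntenic) < 2:
        raise ValueError("n_lnc too small to plant a unique winner")
    winner, s2, s3 = syntenic[0], syntenic[1], syntenic[2]
    ns1, ns2 = non_syntenic[0], non_syntenic[1]

    gene_ids = [a.gene_id for a in annot_a]
    biotype_of = {a.gene_id: a.biotype for a in annot_a}
    enriched = {winner, s2, ns1}
    pc_gene = next(g for g in gene_ids if biotype_of[g] == "protein_coding")
    brain_specific = {winner, s3, pc_gene}

    base = np.exp(rng.uniform(np.log(50.0), np.log(1000.0), size=len(gene_ids)))
    mu_a = base.copy()
    mu_b = base.copy()
    planted_idx = [gene_ids.index(g) for g in enriched]
    mu_b[planted_idx] *= 2.0**planted_log2fc
    counts = _nb_count_matrix(rng, mu_a, mu_b, n_per_group, dispersion)
    sample_ids = [f"neg{j}" for j in range(n_per_group)] + [
        f"pos{j}" for j in range(n_per_group)
    ]
    group_of = {s: (GROUP_NEUN_NEG if s.startswith("neg") else GROUP_NEUN_POS)
                for s in sample_ids}
    cm = CountMatrix(gene_ids, sample_ids, counts, group_of, biotype_of)
    profile = _tissue_profile(rng, gene_ids, base, brain_specific)

    truth = replace(
        homolog_truth,
        enriched_gene_ids=enriched,
        brain_specific_ids=brain_specific,
        funnel_winner_id=winner,
    )
    return FunnelDataset(cm, profile, annot_a, annot_b, seqs_a, seqs_b, truth)
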