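"""Cross-species lncRNA homology calling.

A lncRNA pair is called homologous when (i) the two genes sit in a shared
syntenic locus — the species-B gene lies between the orthologs of the
species-A gene's nearest protein-coding neighbours — and (ii) their
sequence similarity reaches a threshold (default 40%, inclusive).

Similarity is computed from a Smith-Waterman local alignment
(match +1, mismatch -1, linear gap -2 by default) as the number of
identically aligned bases divided by the length of the shorter sequence.
Normalizing by the shorter sequence rather than by alignment columns
means a short, spurious high-identity segment between otherwise unrelated
sequences cannot clear the threshold.  Among equal-score optimal
alignments the one with the most matches is used, which makes the
similarity value well defined; strand of lncRNA annotation is treated as
unreliable, so both strands of the candidate are aligned and the better
one kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import GeneAnnotation, revcomp

__all__ = [
    "HomologCall",
    "align_similarity",
    "syntenic_partner",
    "call_homologs",
    "DEFAULT_SCORING",
    "SIMILARITY_MIN",
]

#: (match, mismatch, gap) scores for the local alignment
DEFAULT_SCORING: tuple[float, float, float] = (1.0, -1.0, -2.0)

#: minimum similarity for a homolog call (inclusive)
SIMILARITY_MIN = 0.40


@dataclass(frozen=True)
class HomologCall:
    query_id: str
    subject_id: str
    similarity: float
    syntenic: bool
    is_homolog: bool

    def __post_init__(self) -> None:
        if self.is_homolog and not self.syntenic:
            raise ValueError("is_homolog requires synteny")


def _local_align_matches(
    a: str, b: str, scoring: tuple[float, float, float]
) -> tuple[float, int]:
    """Best Smith-Waterman score and the max match count over all
    optimal-score local alignments (lexicographic DP objective)."""
    match, mismatch, gap = scoring
    n, m = len(a), len(b)
    # H[j]: best score ending at (i, j); M[j]: max matches on such a path
    prev_h = [0.0] * (m + 1)
    prev_m = [0] * (m + 1)
    best_h, best_m = 0.0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur_h = [0.0] * (m + 1)
        cur_m = [0] * (m + 1)
        for j in range(1, m + 1):
            bj = b[j - 1]
            is_match = ai == bj and ai != "N" and bj != "N"
            sub = match if is_match else mismatch
            h, mm = 0.0, 0  # restart option
            cand_h = prev_h[j - 1] + sub
            cand_m = prev_m[j - 1] + (1 if is_match else 0)
            if cand_h > h or (cand_h == h and cand_m > mm):
                h, mm = cand_h, cand_m
            cand_h = prev_h[j] + gap
            if cand_h > h or (cand_h == h and prev_m[j] > mm):
                h, mm = cand_h, prev_m[j]
            cand_h = cur_h[j - 1] + gap
            if cand_h > h or (cand_h == h and cur_m[j - 1] > mm):
                h, mm = cand_h, cur_m[j - 1]
            cur_h[j], cur_m[j] = h, mm
            if h > best_h or (h == best_h and mm > best_m):
                best_h, best_m = h, mm
        prev_h, prev_m = cur_h, cur_m
    return best_h, best_m


def align_similarity(
    seq_a: str,
    seq_b: str,
    scoring: tuple[float, float, float] = DEFAULT_SCORING,
) -> float:
    """Local-alignment similarity of two nucleotide sequences in [0, 1].

    Matches in the optimal local alignment divided by the length of the
    shorter sequence; 0 when no positive-scoring local alignment exists.
    N never matches anything.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    score, matches = _local_align_matches(seq_a, seq_b, scoring)
    if score <= 0:
        return 0.0
    return matches / min(len(seq_a), len(seq_b))


def _index_annotations(annot: Sequence[GeneAnnotation]) -> dict[str, GeneAnnotation]:
    return {a.gene_id: a for a in annot}


def _flanking_coding_neighbors(
    lnc: GeneAnnotation, annot_a: Sequence[GeneAnnotation]
) -> tuple[GeneAnnotation | None, GeneAnnotation | None]:
    """Nearest protein-coding genes up- and downstream of the lncRNA on
    its chromosome (by genomic coordinate, strand-agnostic)."""
    up = down = None
    for g in annot_a:
        if g.biotype != "protein_coding" or g.interval.chrom != lnc.interval.chrom:
            continue
        if g.interval.end <= lnc.interval.start:
            if up is None or g.interval.end > up.interval.end:
                up = g
        elif g.interval.start >= lnc.interval.end:
            if down is None or g.interval.start < down.interval.start:
                down = g
    return up, down


def syntenic_partner(
    lnc: GeneAnnotation,
    annot_a: Sequence[GeneAnnotation],
    annot_b: Sequence[GeneAnnotation],
) -> list[GeneAnnotation]:
    """Species-B lncRNAs lying between the orthologs of the species-A
    lncRNA's nearest protein-coding flanks (either block orientation).

    Empty when either flank is missing or lacks an ortholog link.
    """
    by_id_a = _index_annotations(annot_a)
    if lnc.gene_id not in by_id_a:
        raise ValueError(f"lncRNA {lnc.gene_id!r} not in species-A annotation")
    up, down = _flanking_coding_neighbors(lnc, annot_a)
    if up is None or down is None or up.ortholog_id is None or down.ortholog_id is None:
        return []
    by_id_b = _index_annotations(annot_b)
    orth_u = by_id_b.get(up.ortholog_id)
    orth_d = by_id_b.get(down.ortholog_id)
    if orth_u is None or orth_d is None:
        return []
    if orth_u.interval.chrom != orth_d.interval.chrom:
        return []
    lo = min(orth_u.interval.end, orth_d.interval.end)
    hi = max(orth_u.interval.start, orth_d.interval.start)
    if lo > hi:
        return []
    return [
        g
        for g in annot_b
        if g.biotype == "lncRNA"
        and g.interval.chrom == orth_u.interval.chrom
        and g.interval.start >= lo
        and g.interval.end <= hi
    ]


def call_homologs(
    annot_a: Sequence[GeneAnnotation],
    seqs_a: Mapping[str, str],
    annot_b: Sequence[GeneAnnotation],
    seqs_b: Mapping[str, str],
    similarity_min: float = SIMILARITY_MIN,
    scoring: tuple[float, float, float] = DEFAULT_SCORING,
) -> list[HomologCall]:
    """One best-partner homology call per species-A lncRNA with at least
    one syntenic candidate.

    Both strands of each candidate are aligned and the higher similarity
    kept.  The best partner is chosen by similarity, ties broken by
    smaller genomic distance between the candidate and the syntenic-block
    midpoint, then lexicographic id.  ``is_homolog`` requires similarity
    >= ``similarity_min`` (inclusive).
    """
    calls: list[HomologCall] = []
    for lnc in annot_a:
        if lnc.biotype != "lncRNA":
            continue
        candidates = syntenic_partner(lnc, annot_a, annot_b)
        if not candidates:
            continue
        if lnc.gene_id not in seqs_a:
            raise ValueError(f"no sequence for species-A lncRNA {lnc.gene_id!r}")
        query_seq = seqs_a[lnc.gene_id]
        block_mid = sum(c.interval.midpoint for c in candidates) / len(candidates)
        scored: list[tuple[float, float, str]] = []
        for cand in candidates:
            if cand.gene_id not in seqs_b:
                raise ValueError(
                    f"no sequence for species-B lncRNA {cand.gene_id!r}"
                )
            s = seqs_b[cand.gene_id]
            sim = max(
                align_similarity(query_seq, s, scoring),
                align_similarity(query_seq, revcomp(s), scoring),
            )
            scored.append((sim, abs(cand.interval.midpoint - block_mid), cand.gene_id))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        sim, _, subject = scored[0]
        calls.append(
            HomologCall(
                query_id=lnc.gene_id,
                subject_id=subject,
                similarity=sim,
                syntenic=True,
                is_homolog=sim >= similarity_min,
            )
        )
    return calls
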