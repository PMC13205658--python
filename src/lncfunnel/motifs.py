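"""Promoter motif analysis.

Promoters are the ``upstream`` bases before each TSS (default 1000 bp),
read toward the TSS.  PFMs become log-odds position weight matrices with
a background-distributed pseudocount; scan stringency is set by an exact
p-value on the background score distribution, computed by dynamic
programming over discretized scores (bin width 1e-3), so scans are
reproducible without an external matcher.  The coverage statistic asks
what fraction of a gene set carries at least one promoter hit for any of
a panel of transcription factors.  G-quadruplex candidates are called
with the classical pattern rule (four runs of >= 3 G separated by 1-7 nt
loops) on both strands.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneAnnotation, PFMRecord, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "MotifHit",
    "CoverageReport",
    "extract_promoters",
    "build_pwm",
    "pwm_score_threshold",
    "scan_pwm",
    "tf_coverage",
    "find_quadruplexes",
    "UNIFORM_BACKGROUND",
    "SCORE_BIN",
]

UNIFORM_BACKGROUND = np.full(4, 0.25)

#: discretization width for the exact score-distribution DP
SCORE_BIN = 1e-3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """Log-odds position weight matrix (rows A, C, G, T)."""

    motif_id: str
    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[0] != 4:
            raise ValueError("log_odds must be 4 x L")
        if not np.isfinite(self.log_odds).all():
            raise ValueError("log_odds must be finite")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def __len__(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based on the forward sequence
    strand: str
    score: float


@dataclass
class CoverageReport:
    """Which genes of a set are 'explained' by promoter hits of a TF panel."""

    explained_by_tf: dict[str, set[str]]
    union_explained: set[str]
    unexplained: set[str]
    fraction: float


def build_pwm(
    pfm: PFMRecord,
    background: np.ndarray | Sequence[float] = UNIFORM_BACKGROUND,
    pseudocount: float = 0.8,
) -> PWM:
    """PFM -> log2-odds PWM with the pseudocount distributed by background."""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a 4-vector of probabilities")
    if (bg <= 0).any():
        raise ValueError("background probabilities must be strictly positive")
    counts = pfm.counts
    col_total = counts.sum(axis=0)
    freq = (counts + pseudocount * bg[:, None]) / (col_total + pseudocount)
    log_odds = np.log2(freq / bg[:, None])
    return PWM(pfm.motif_id, log_odds, bg, pseudocount)


def _discretized_columns(pwm: PWM) -> np.ndarray:
    """Column scores in integer units of SCORE_BIN."""
    return np.round(pwm.log_odds / SCORE_BIN).astype(np.int64)


def pwm_score_threshold(pwm: PWM, pvalue: float) -> float:
    """Smallest score s with P(background L-mer scores >= s) <= pvalue.

    The background score distribution is computed exactly on a 1e-3
    score grid by column-wise convolution.  When even the maximum score
    is more probable than ``pvalue`` the returned threshold exceeds the
    maximum, so no window can pass.
    """
    if pvalue <= 0:
        raise ValueError("pvalue must be positive")
    q = _discretized_columns(pwm)
    L = q.shape[1]
    if L > 25:
        raise ValueError("exact threshold supported for motif length <= 25")
    prefix_lo, prefix_hi = 0, 0
    dist = np.array([1.0])  # empty prefix: score 0 with probability 1
    for i in range(L):
        col = q[:, i]
        new_lo = prefix_lo + int(col.min())
        new_hi = prefix_hi + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = prefix_lo + int(col[b]) - new_lo
            new[shift : shift + dist.size] += pwm.background[b] * dist
        dist = new
        prefix_lo, prefix_hi = new_lo, new_hi
    tail = np.cumsum(dist[::-1])[::-1]  # tail[k] = P(score >= prefix_lo + k)
    achievable = np.nonzero((dist > 0) & (tail <= pvalue))[0]
    if achievable.size == 0:
        return (prefix_hi + 1) * SCORE_BIN
    return (prefix_lo + int(achievable[0])) * SCORE_BIN


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(
    log_odds: np.ndarray, enc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Float and grid-discretized scores of every length-L window.

    Windows containing N get NaN / minimal grid score.
    """
    L = log_odds.shape[1]
    q = np.round(log_odds / SCORE_BIN).astype(np.int64)
    n_win = enc.size - L + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    scores = np.zeros(n_win)
    grid = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(enc >= 0, enc, 0)
    for i in range(L):
        window_bases = safe[i : i + n_win]
        scores += log_odds[window_bases, i]
        grid += q[window_bases, i]
        valid &= enc[i : i + n_win] >= 0
    scores[~valid] = np.nan
    grid[~valid] = np.iinfo(np.int64).min
    return scores, grid


def scan_pwm(
    pwm: PWM, seqs: Mapping[str, str], threshold: float
) -> list[MotifHit]:
    """All windows on both strands scoring >= threshold.

    Reverse-strand hits are reported at the forward-strand offset of the
    window; windows containing N are skipped.  The comparison happens on
    the same 1e-3 score grid the exact threshold is computed on, so a
    DP-derived threshold admits exactly the windows its tail probability
    counts; the reported score is the exact float log-odds sum.
    """
    L = len(pwm)
    grid_threshold = int(round(threshold / SCORE_BIN))
    # reverse-complement scan == scanning with the row- and column-reversed
    # matrix (A<->T, C<->G is row reversal in A,C,G,T order)
    rc_log_odds = pwm.log_odds[::-1, ::-1]
    hits: list[MotifHit] = []
    for seq_id, seq in seqs.items():
        if len(seq) < L:
            continue
        enc = _encode(seq)
        for strand, mat in (("+", pwm.log_odds), ("-", rc_log_odds)):
            scores, grid = _window_scores(mat, enc)
            idx = np.nonzero(grid >= grid_threshold)[0]
            for off in idx:
                hits.append(MotifHit(seq_id, int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h.seq_id, h.offset, h.strand))
    return hits


def tf_coverage(
    gene_set: Iterable[str], hits_by_tf: Mapping[str, set[str]]
) -> CoverageReport:
    """Per-TF and union 'explained' partition of a gene set."""
    genes = set(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    explained: dict[str, set[str]] = {}
    for tf, hit_genes in hits_by_tf.items():
        extra = set(hit_genes) - genes
        if extra:
            logger.info(
                "%s: ignoring %d hit gene(s) outside the gene set", tf, len(extra)
            )
        explained[tf] = set(hit_genes) & genes
    union = set().union(*explained.values()) if explained else set()
    return CoverageReport(
        explained_by_tf=explained,
        union_explained=union,
        unexplained=genes - union,
        fraction=len(union) / len(genes),
    )


_G4_FORWARD = re.compile(r"G{3,}(?:[ACGTN]{1,7}G{3,}){3}")


def find_quadruplexes(seq: str) -> list[tuple[int, int, str]]:
    """G-quadruplex candidates on both strands by the pattern rule.

    Four runs of >= 3 G separated by loops of 1-7 nt; overlaps resolved
    greedily left to right on each strand.  Reverse-strand (C-quadruplex)
    matches are reported in forward coordinates.
    """
    seq = seq.upper()
    out = [(m.start(), m.end(), "+") for m in _G4_FORWARD.finditer(seq)]
    n = len(seq)
    for m in _G4_FORWARD.finditer(revcomp(seq)):
        out.append((n - m.end(), n - m.start(), "-"))
    out.sort()
    return out


def extract_promoters(
    annot: Sequence[GeneAnnotation],
    genome: Mapping[str, str],
    upstream: int = 1000,
) -> dict[str, str]:
    """Promoter sequences (``upstream`` bp before the TSS), keyed by gene.

    Plus-strand genes give the genomic window [tss - upstream, tss);
    minus-strand genes the window (tss, tss + upstream], reverse-
    complemented so every promoter reads toward the TSS.  Windows are
    clipped at chromosome ends and short windows logged.
    """
    out: dict[str, str] = {}
    for gene in annot:
        chrom = gene.interval.chrom
        if chrom not in genome:
            raise ValueError(f"gene {gene.gene_id!r} on missing chromosome {chrom!r}")
        seq = genome[chrom]
        tss = gene.tss
        if gene.interval.strand == "+":
            start = max(0, tss - upstream)
            window = seq[start:tss]
        else:
            end = min(len(seq), tss + 1 + upstream)
            window = revcomp(seq[tss + 1 : end])
        if len(window) < upstream:
            logger.warning(
                "promoter of %s clipped to %d bp", gene.gene_id, len(window)
            )
        out[gene.gene_id] = window
    return out
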