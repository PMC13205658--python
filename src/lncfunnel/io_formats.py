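"""Readers and writers for the plain-text formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals;
conversion to and from 1-based inclusive GTF coordinates happens only here,
at the I/O boundary.  The TSS of a ``+`` gene is ``start``; of a ``-`` gene
it is ``end - 1``, so both definitions point at the first transcribed base.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "PFMRecord",
    "parse_gene_annotation",
    "write_bed",
    "write_gtf",
    "parse_fasta",
    "write_fasta",
    "parse_pfm",
    "write_pfm",
    "revcomp",
]

IUPAC_NT = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence (IUPAC aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene locus with biotype and an optional cross-species ortholog link."""

    gene_id: str
    interval: GenomicInterval
    biotype: str = "other"
    ortholog_id: str | None = None

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass
class PFMRecord:
    """A position frequency matrix over the alphabet A, C, G, T."""

    motif_id: str
    tf_name: str
    counts: np.ndarray  # shape (4, L), rows in A,C,G,T order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("PFM counts must be a 4 x L matrix")
        if self.counts.shape[1] < 1:
            raise ValueError("PFM must have at least one column")
        if (self.counts < 0).any():
            raise ValueError(f"negative count in PFM {self.motif_id}")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(
                f"PFM {self.motif_id} has a column with zero total count"
            )

    def __len__(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


_KNOWN_BIOTYPES = {"protein_coding", "lncRNA"}


def _normalize_biotype(raw: str | None) -> str:
    if raw in _KNOWN_BIOTYPES:
        return raw
    return "other"


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gene_annotation(path: str | Path, dialect: str) -> list[GeneAnnotation]:
    """Read gene annotations from a GTF or BED file.

    GTF coordinates (1-based, end-inclusive) are converted to the internal
    0-based half-open convention; BED is already 0-based half-open and is
    passed through.  Biotype is taken from the ``gene_biotype`` /
    ``gene_type`` GTF attribute when present, and an ``ortholog_id``
    attribute is honoured for cross-species links; unknown biotypes map
    to ``other``.
    """
    dialect = dialect.upper()
    if dialect not in ("GTF", "BED"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    out: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "GTF":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated fields")
                    chrom, _source, _feature = fields[0], fields[1], fields[2]
                    start1, end1 = int(fields[3]), int(fields[4])
                    strand = fields[6]
                    attrs = _parse_gtf_attributes(fields[8])
                    gene_id = attrs.get("gene_id")
                    if gene_id is None:
                        raise ValueError("missing gene_id attribute")
                    interval = GenomicInterval(chrom, start1 - 1, end1, strand)
                    biotype = _normalize_biotype(
                        attrs.get("gene_biotype") or attrs.get("gene_type")
                    )
                    ortholog = attrs.get("ortholog_id")
                else:  # BED
                    if len(fields) < 6:
                        raise ValueError(
                            "expected at least 6 tab-separated BED fields"
                        )
                    chrom = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    gene_id = fields[3]
                    strand = fields[5]
                    interval = GenomicInterval(chrom, start, end, strand)
                    biotype = _normalize_biotype(
                        fields[6] if len(fields) > 6 else None
                    )
                    ortholog = (
                        fields[7] if len(fields) > 7 and fields[7] != "." else None
                    )
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            if gene_id in seen:
                raise ValueError(f"{path}, line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            out.append(GeneAnnotation(gene_id, interval, biotype, ortholog))
    return out


def write_bed(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            iv = a.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        a.gene_id,
                        "0",
                        iv.strand,
                        a.biotype,
                        a.ortholog_id or ".",
                    ]
                )
                + "\n"
            )


def write_gtf(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            iv = a.interval
            attrs = f'gene_id "{a.gene_id}"; gene_biotype "{a.biotype}";'
            if a.ortholog_id:
                attrs += f' ortholog_id "{a.ortholog_id}";'
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "lncfunnel",
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def parse_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered mapping of id -> uppercase sequence.

    Duplicate ids and non-IUPAC characters are rejected.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in IUPAC_NT:
                raise ValueError(
                    f"non-IUPAC character {ch!r} at position {pos} "
                    f"of sequence {record.id!r}"
                )
        seqs[record.id] = seq
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def parse_pfm(path: str | Path) -> list[PFMRecord]:
    """Read JASPAR-style PFM text (``>ID NAME`` then labelled A/C/G/T rows).

    Rows may appear in any order in the file; the returned matrices are
    always in A, C, G, T row order.
    """
    records: list[PFMRecord] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}

    def _flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        missing = set("ACGT") - set(rows)
        if missing:
            raise ValueError(
                f"PFM {header[0]} missing rows for {sorted(missing)}"
            )
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"PFM {header[0]} has rows of unequal length")
        counts = np.array([rows[b] for b in "ACGT"], dtype=float)
        records.append(PFMRecord(header[0], header[1], counts))
        header, rows = None, {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
            else:
                if header is None:
                    raise ValueError(f"{path}, line {lineno}: row before header")
                base, _, rest = line.partition(" ")
                base = base.strip().upper()
                if base not in "ACGT" or len(base) != 1:
                    raise ValueError(
                        f"{path}, line {lineno}: unexpected row label {base!r}"
                    )
                values = rest.replace("[", " ").replace("]", " ").split()
                try:
                    rows[base] = [float(v) for v in values]
                except ValueError as exc:
                    raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    _flush()
    if not records:
        raise ValueError(f"no PFM records found in {path}")
    return records


def write_pfm(records: Iterable[PFMRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.motif_id} {rec.tf_name}\n")
            for base, row in zip("ACGT", rec.counts):
                body = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {body} ]\n")
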