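"""Core domain types shared by every pipeline stage.

Coordinates are 1-based and inclusive at both ends (GTF native), so an
interval of a single base has ``start == end`` and length 1. All interval
arithmetic in the package assumes this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """Coordinate gap between the spans; 0 when they overlap.

        For a non-overlapping neighbour the distance is the difference
        between the facing coordinates (an immediately adjacent feature is
        at distance 1). Returns None for features on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start > self.end:
            return other.start - self.end
        return self.start - other.end


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript; the unit of the cascade."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    biotype: str = "unknown"  # protein_coding | lncRNA_annotated | unknown

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        prev_end = 0
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon not on transcript chrom/strand"
                )
            if ex.start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        if (
            self.interval.start != self.exons[0].start
            or self.interval.end != self.exons[-1].end
        ):
            raise ValueError(
                f"{self.transcript_id}: interval does not span exactly its exons"
            )

    @classmethod
    def from_exons(
        cls,
        transcript_id: str,
        gene_id: str,
        exons: Iterable[GenomicInterval],
        biotype: str = "unknown",
    ) -> "TranscriptModel":
        exs = sorted(exons, key=lambda e: e.start)
        iv = GenomicInterval(
            exs[0].chrom, exs[0].start, exs[-1].end, exs[0].strand
        )
        return cls(transcript_id, gene_id, iv, exs, biotype)

    @property
    def length(self) -> int:
        """Mature transcript length: the sum of exon lengths."""
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start - a.end > 1:
                out.append(
                    GenomicInterval(
                        self.interval.chrom, a.end + 1, b.start - 1,
                        self.interval.strand,
                    )
                )
        return out

    def exonic_overlap(self, other: "TranscriptModel") -> bool:
        """True iff any exon of self overlaps any exon of other (strand-blind)."""
        for a in self.exons:
            for b in other.exons:
                if a.overlaps(b):
                    return True
        return False


class ExpressionMatrix:
    """Transcripts x samples table of counts or FPKM with a sample design.

    Thin wrapper over a pandas DataFrame (rows = transcripts, columns =
    samples) carrying the sample -> condition mapping and the value kind.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        design: Mapping[str, str],
        kind: str = "counts",
    ) -> None:
        if kind not in ("counts", "fpkm"):
            raise ValueError("kind must be 'counts' or 'fpkm'")
        missing = [s for s in values.columns if s not in design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        arr = values.to_numpy()
        if arr.size:
            if np.any(arr < 0):
                raise ValueError("expression values must be non-negative")
            if kind == "counts" and not np.allclose(
                arr.astype(float), np.round(arr.astype(float))
            ):
                raise ValueError("counts must be integers")
        self.values = values.copy()
        self.design = {s: design[s] for s in values.columns}
        self.kind = kind

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.design[s], None)
        return list(seen)

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.design[s] == condition]

    def subset(self, transcript_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(transcript_ids)
        missing = [t for t in ids if t not in self.values.index]
        if missing:
            raise KeyError(f"transcripts not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[ids], self.design, self.kind)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix(kind={self.kind}, "
            f"{self.values.shape[0]}x{self.values.shape[1]})"
        )


@dataclass
class CodingPotential:
    """ORF-based coding-potential call for one transcript."""

    transcript_id: str
    longest_orf_nt: int
    orf_coverage: float
    score: float
    is_coding: bool


@dataclass
class LncRNARecord:
    """A transcript that survived the identification cascade."""

    transcript: TranscriptModel
    cls: str  # lincRNA | lncNAT | sense_overlapping | intronic
    status: str  # novel | annotated


@dataclass
class DEResult:
    transcript_id: str
    base_mean: float
    log2fc: float
    p: float
    q: float
    call: str  # up | down | ns


@dataclass(frozen=True)
class TargetPair:
    lncrna_id: str
    gene_id: str
    mode: str  # cis | trans
    distance: int | None = None
    pcc: float | None = None
    p: float | None = None


@dataclass(frozen=True)
class MiRNATargetHit:
    mirna_id: str
    target_id: str
    target_kind: str  # lncRNA | mRNA
    site_start: int  # 1-based on target
    alignment: str
    score: float


@dataclass(frozen=True)
class CeRNATriplet:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
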