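"""lncRNA identification: the five-round filter cascade plus classification.

Candidate transcript models are filtered in a fixed order — (0) certain
strand, (1) >=2 exons, (2) mature length >= 200 nt, (3) annotation overlap
resolution, (4) FPKM >= 0.5 in at least one sample, (5) no protein-coding
potential — and the survivors are classified as lincRNA, lncNAT,
sense_overlapping or intronic by explicit coordinate rules.

Coding potential is an ORF-length/coverage rule (a documented stand-in for
external coding-potential classifiers); precomputed is_coding labels can be
supplied instead, so output from external tools plugs straight in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    CodingPotential,
    ExpressionMatrix,
    LncRNARecord,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

CASCADE_STEPS = (
    "strand_certain",
    "exon_count",
    "min_length",
    "annotation_overlap",
    "min_fpkm",
    "noncoding",
)


def longest_orf(sequence: str) -> tuple[int, int | None, int | None, int | None]:
    """Longest ATG->stop open reading frame over the 3 forward frames.

    Returns (length_nt, frame, start, end) with 1-based inclusive start/end
    on the given (already oriented) sequence; length includes the stop
    codon. Returns (0, None, None, None) when no complete ORF exists.
    """
    seq = sequence.upper()
    best = (0, None, None, None)
    n = len(seq)
    if n < 6:
        return best
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in STOP_CODONS:
                length = i + 3 - open_start
                if length > best[0]:
                    best = (length, frame, open_start + 1, i + 3)
                open_start = None
    return best


def coding_potential(
    sequence: str,
    transcript_id: str = "",
    w_orf: float = 1.0,
    w_cov: float = 1.0,
    orf_coding_nt: int = 300,
    orf_suspect_nt: int = 200,
    cov_suspect: float = 0.5,
) -> CodingPotential:
    """Score coding potential from ORF length and ORF coverage.

    score = w_orf * (longest_orf/300) + w_cov * orf_coverage. A transcript is
    called coding when its longest ORF is >= 300 nt, or >= 200 nt while also
    covering >= 50% of the transcript. Thresholds are inclusive.
    """
    orf_nt = longest_orf(sequence)[0]
    cov = orf_nt / len(sequence) if sequence else 0.0
    score = w_orf * (orf_nt / orf_coding_nt) + w_cov * cov
    is_coding = orf_nt >= orf_coding_nt or (
        orf_nt >= orf_suspect_nt and cov >= cov_suspect
    )
    return CodingPotential(transcript_id, orf_nt, cov, score, is_coding)


@dataclass
class FilterStep:
    name: str
    n_input: int
    n_removed: int
    removed_ids: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    """Per-step accounting for the cascade; counts telescope."""

    steps: list[FilterStep]
    surviving_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [s.name for s in self.steps],
                "n_input": [s.n_input for s in self.steps],
                "n_removed": [s.n_removed for s in self.steps],
                "n_surviving": [s.n_input - s.n_removed for s in self.steps],
            }
        )

    def validate(self) -> None:
        for a, b in zip(self.steps, self.steps[1:]):
            if a.n_input - a.n_removed != b.n_input:
                raise AssertionError("filter report counts do not telescope")
        last = self.steps[-1]
        if last.n_input - last.n_removed != len(self.surviving_ids):
            raise AssertionError("final step does not match surviving set")


def _exon_chains_equal(a: TranscriptModel, b: TranscriptModel) -> bool:
    return (
        a.interval.chrom == b.interval.chrom
        and a.interval.strand == b.interval.strand
        and len(a.exons) == len(b.exons)
        and all(
            x.start == y.start and x.end == y.end for x, y in zip(a.exons, b.exons)
        )
    )


def classify_lncrna(
    transcript: TranscriptModel,
    protein_coding_genes: Sequence[TranscriptModel],
) -> str:
    """Positional class of a surviving lncRNA relative to coding genes.

    lncNAT: >=1 bp exonic overlap with a coding exon on the opposite strand.
    intronic: fully inside an intron of a coding gene, no exonic overlap.
    sense_overlapping: span overlap with a coding gene without exonic overlap.
    lincRNA: no span overlap with any coding gene on either strand.
    """
    span_hits = [
        g
        for g in protein_coding_genes
        if g.interval.overlaps(transcript.interval)
    ]
    if not span_hits:
        return "lincRNA"
    for g in span_hits:
        if g.interval.strand != transcript.interval.strand and transcript.exonic_overlap(g):
            return "lncNAT"
    for g in span_hits:
        if any(intr.contains(transcript.interval) for intr in g.introns()):
            return "intronic"
    return "sense_overlapping"


def filter_cascade(
    candidates: Sequence[TranscriptModel],
    fpkm: ExpressionMatrix,
    annotation: Sequence[TranscriptModel],
    coding: Mapping[str, CodingPotential] | Sequence[CodingPotential],
    exon_min: int = 2,
    len_min: int = 200,
    fpkm_min: float = 0.5,
    fpkm_agg: str = "max",
) -> tuple[list[LncRNARecord], FilterReport]:
    """Apply the five-round identification cascade in order.

    Thresholds are inclusive (>=). The annotation-overlap round removes
    candidates whose exons overlap an annotated protein-coding exon on the
    same strand; candidates whose exon chain exactly matches an annotated
    lncRNA are kept with status "annotated", all other survivors are
    "novel". ``fpkm_agg`` selects how per-sample FPKM is aggregated for the
    expression round: "max" (default), "mean" or "all".
    """
    if fpkm_agg not in ("max", "mean", "all"):
        raise ValueError("fpkm_agg must be 'max', 'mean' or 'all'")
    if not isinstance(coding, Mapping):
        coding = {c.transcript_id: c for c in coding}

    for t in candidates:
        if t.transcript_id not in fpkm.values.index:
            raise KeyError(f"candidate {t.transcript_id} missing from FPKM matrix")
        if t.transcript_id not in coding:
            raise KeyError(f"candidate {t.transcript_id} missing coding score")

    coding_ann = [a for a in annotation if a.biotype == "protein_coding"]
    lnc_ann = [a for a in annotation if a.biotype == "lncRNA_annotated"]
    exons_by_chrom: dict[tuple[str, str], list] = {}
    for g in coding_ann:
        for ex in g.exons:
            exons_by_chrom.setdefault((ex.chrom, ex.strand), []).append(ex)

    steps: list[FilterStep] = []
    alive = list(candidates)

    def run_step(name: str, keep_fn) -> None:
        nonlocal alive
        kept, removed = [], []
        for t in alive:
            (kept if keep_fn(t) else removed).append(t)
        steps.append(
            FilterStep(name, len(alive), len(removed), [t.transcript_id for t in removed])
        )
        alive = kept

    run_step("strand_certain", lambda t: t.interval.strand in ("+", "-"))
    run_step("exon_count", lambda t: t.n_exons >= exon_min)
    run_step("min_length", lambda t: t.length >= len_min)

    def no_coding_overlap(t: TranscriptModel) -> bool:
        pool = exons_by_chrom.get((t.interval.chrom, t.interval.strand), [])
        return not any(ex.overlaps(ae) for ex in t.exons for ae in pool)

    run_step("annotation_overlap", no_coding_overlap)

    vals = fpkm.values

    def expressed(t: TranscriptModel) -> bool:
        row = vals.loc[t.transcript_id].to_numpy(dtype=float)
        if fpkm_agg == "max":
            stat = row.max()
        elif fpkm_agg == "mean":
            stat = row.mean()
        else:
            stat = row.min()
        return bool(stat >= fpkm_min)

    run_step("min_fpkm", expressed)
    run_step("noncoding", lambda t: not coding[t.transcript_id].is_coding)

    records: list[LncRNARecord] = []
    for t in alive:
        status = (
            "annotated"
            if any(_exon_chains_equal(t, a) for a in lnc_ann)
            else "novel"
        )
        records.append(
            LncRNARecord(t, classify_lncrna(t, coding_ann), status)
        )
    report = FilterReport(steps, [t.transcript_id for t in alive])
    report.validate()
    return records, report


# ---------------------------------------------------------------------------
# Characterization (population summaries of the identified sets)

LENGTH_BINS = [0, 200, 400, 600, 800, 1000, 1500, 2000, 2500, 3000, np.inf]
ORF_BINS = [0, 100, 200, 300, 400, 500, 700, 1000, np.inf]


def _hist(values: list, bins: list, labels: list[str]) -> pd.Series:
    if not values:
        return pd.Series(0.0, index=labels)
    cut = pd.cut(values, bins=bins, labels=labels, right=False, include_lowest=True)
    counts = cut.value_counts().reindex(labels).fillna(0)
    return counts / counts.sum()


def characterize(
    lncrnas: Sequence[TranscriptModel],
    mrnas: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
) -> dict[str, pd.DataFrame]:
    """Population summaries: exon count, chromosome, length and ORF length.

    Returns one DataFrame per axis with a proportion column per population;
    proportions sum to 1 within each non-empty column.
    """
    pops = {"lncRNA": list(lncrnas), "mRNA": list(mrnas)}
    for name, pop in pops.items():
        if not pop:
            logger.warning("characterize: empty %s population", name)

    exon_labels = [str(i) for i in range(1, 10)] + ["10+"]
    len_labels = _bin_labels(LENGTH_BINS)
    orf_labels = _bin_labels(ORF_BINS)

    out: dict[str, pd.DataFrame] = {}
    out["exon_count"] = pd.DataFrame(
        {
            name: _hist(
                [min(t.n_exons, 10) for t in pop],
                bins=list(range(1, 11)) + [np.inf],
                labels=exon_labels,
            )
            for name, pop in pops.items()
        }
    )
    chroms = sorted(
        {t.interval.chrom for pop in pops.values() for t in pop}
    )
    out["chromosome"] = pd.DataFrame(
        {
            name: (
                pd.Series(
                    [t.interval.chrom for t in pop], dtype="object"
                ).value_counts().reindex(chroms).fillna(0)
                / max(len(pop), 1)
            )
            for name, pop in pops.items()
        }
    ).fillna(0.0)
    out["transcript_length"] = pd.DataFrame(
        {
            name: _hist([t.length for t in pop], LENGTH_BINS, len_labels)
            for name, pop in pops.items()
        }
    )
    out["orf_length"] = pd.DataFrame(
        {
            name: _hist(
                [longest_orf(sequences[t.transcript_id])[0] for t in pop],
                ORF_BINS,
                orf_labels,
            )
            for name, pop in pops.items()
        }
    )
    for df in out.values():
        df.attrs["n"] = {name: len(pop) for name, pop in pops.items()}
    return out


def _bin_labels(bins: list) -> list[str]:
    labels = []
    for a, b in zip(bins, bins[1:]):
        labels.append(f"{int(a)}+" if np.isinf(b) else f"{int(a)}-{int(b)}")
    return labels
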