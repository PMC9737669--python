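"""Synthetic seed-aging transcriptome with fully planted ground truth.

The generator emulates the statistical structure of a two-condition
(aged vs new seed, 3 replicates each) strand-specific RNA-seq study at toy
scale: a protein-coding mRNA population (800-3000 nt, broad exon counts),
a lncRNA population (200-1000 nt, 2-3 exons, ORF <= 200 nt in >90% of
transcripts) split ~2:1 into intergenic lincRNAs and antisense lncNATs,
plus one contaminant class per cascade filter so every identification round
has work to do. Differential expression is planted with a heavy skew toward
lncRNA downregulation (default 90 down, 4 up), miRNA binding sites are
planted as reverse complements in selected lncRNA/mRNA pairs, and a term
map with one genuinely enriched pathway among down-lncRNA targets gives the
enrichment stage a positive control.

Everything is deterministic for a fixed seed; all sub-generators derive
child streams from the single root seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .identify import longest_orf
from .models import ExpressionMatrix, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[a] = b

NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# contaminant classes, one per cascade round
CONTAMINANT_CLASSES = (
    "strand_uncertain",
    "single_exon_artifact",
    "short_fragment",
    "coding_overlap",
    "low_expression_artifact",
    "coding_contaminant",
)


@dataclass
class DEConfig:
    n_up_lnc: int = 4
    n_down_lnc: int = 90
    n_up_mrna: int = 5
    n_down_mrna: int = 60
    lfc_range: tuple[float, float] = (2.0, 4.0)  # |log2FC| of planted effects

    def validate(self) -> None:
        lo, hi = self.lfc_range
        if not (1.0 < lo <= hi):
            raise ValueError("planted |log2FC| range must satisfy 1 < lo <= hi")
        for n in (self.n_up_lnc, self.n_down_lnc, self.n_up_mrna, self.n_down_mrna):
            if n < 0:
                raise ValueError("DE counts must be >= 0")


@dataclass
class SyntheticConfig:
    n_chrom: int = 4
    chrom_length: int = 1_000_000
    n_mrna: int = 200
    n_lncrna: int = 100
    lincrna_fraction: float = 2 / 3
    mrna_exon_range: tuple[int, int] = (1, 12)
    mrna_length_range: tuple[int, int] = (800, 3000)
    lnc_exon_range: tuple[int, int] = (2, 3)
    lnc_length_range: tuple[int, int] = (200, 1000)
    lnc_orf_cap: int = 200
    lnc_long_orf_fraction: float = 0.07  # lncRNAs allowed a 200-280 nt ORF
    n_strand_uncertain: int = 12
    n_single_exon: int = 15
    n_short_fragment: int = 12
    n_coding_overlap: int = 10
    n_low_expression: int = 10
    n_coding_contaminant: int = 8
    annotated_lnc_fraction: float = 0.3
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    de_config: DEConfig = field(default_factory=DEConfig)
    lnc_mean_range: tuple[float, float] = (100.0, 1000.0)
    mrna_mean_range: tuple[float, float] = (200.0, 5000.0)
    library_factor_range: tuple[float, float] = (0.75, 1.35)
    n_mirna: int = 12
    mirna_length: int = 21
    n_planted_triplets: int = 10
    site_wobbles: int = 0  # G:U wobbles planted outside the seed region
    n_terms: int = 20
    enriched_term_size: int = 30
    enriched_term_overlap: int = 20  # term genes drawn from down-DEL targets
    cis_window: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.lincrna_fraction <= 1:
            raise ValueError("lincrna_fraction must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        self.de_config.validate()
        de = self.de_config
        if de.n_up_lnc + de.n_down_lnc > self.n_lncrna:
            raise ValueError("planted lncRNA DE exceeds n_lncrna")
        if de.n_up_mrna + de.n_down_mrna > self.n_mrna:
            raise ValueError("planted mRNA DE exceeds n_mrna")
        n_lncnat = self.n_lncrna - round(self.n_lncrna * self.lincrna_fraction)
        if n_lncnat + self.n_coding_overlap > self.n_mrna:
            raise ValueError("not enough mRNA hosts for lncNATs/overlap contaminants")
        if self.n_planted_triplets > 0 and self.n_mirna == 0:
            raise ValueError("planted triplets need miRNAs")


@dataclass
class SyntheticTruth:
    """Planted labels against which every pipeline stage is tested.

    transcripts: one row per transcript (index = transcript_id) with
    biotype, role (candidate/reference), DE direction and true log2FC,
    base mean and expected cascade fate ("pass" or the removing step).
    sites: one row per planted miRNA binding site.
    """

    transcripts: pd.DataFrame
    sites: pd.DataFrame

    def candidate_ids(self) -> list[str]:
        return list(self.transcripts.index[self.transcripts["role"] == "candidate"])

    def pass_ids(self) -> set[str]:
        t = self.transcripts
        return set(t.index[(t["role"] == "candidate") & (t["fate"] == "pass")])

    def de_ids(self, direction: str, biotype_prefix: str | None = None) -> set[str]:
        t = self.transcripts
        mask = t["de"] == direction
        if biotype_prefix == "lncRNA":
            mask &= t["biotype"].isin(["lincRNA", "lncNAT"])
        elif biotype_prefix == "mRNA":
            mask &= t["biotype"] == "mRNA"
        return set(t.index[mask])


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    annotation: list[TranscriptModel]
    candidates: list[TranscriptModel]
    genome: dict[str, str]
    transcript_seqs: dict[str, str]
    mirnas: dict[str, str]
    counts: ExpressionMatrix
    terms: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# internals

def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[::-1]]


def _revcomp(seq: str) -> str:
    return _revcomp_arr(np.frombuffer(seq.encode(), dtype=np.uint8)).tobytes().decode()


def rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class _Locus:
    transcript: TranscriptModel
    cls: str  # mRNA | lincRNA | lncNAT | contaminant class
    all_idx: np.ndarray  # 0-based plus-strand genomic indices of exon bases
    owned: np.ndarray  # bool mask over all_idx: bases this locus may write
    host: str | None = None  # host mRNA for attached loci


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(NON_STOP_CODONS), size=max(n, 0))
    return "".join(NON_STOP_CODONS[i] for i in idx)


def _split_length(rng: np.random.Generator, total: int, k: int, min_len: int) -> list[int]:
    if k == 1:
        return [total]
    w = rng.dirichlet(np.ones(k))
    lens = (w * (total - min_len * k)).astype(int) + min_len
    lens[-1] += total - int(lens.sum())
    return [int(x) for x in lens]


def _exon_intervals(
    chrom: str, start: int, strand: str, exon_lens: list[int], intron_lens: list[int]
) -> list[GenomicInterval]:
    out = []
    pos = start
    for i, el in enumerate(exon_lens):
        out.append(GenomicInterval(chrom, pos, pos + el - 1, strand))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return out


class _Builder:
    def __init__(self, config: SyntheticConfig):
        config.validate()
        self.cfg = config
        self.place_rng = _rng(config, 0)
        self.seq_rng = _rng(config, 1)
        self.de_rng = _rng(config, 2)
        self.site_rng = _rng(config, 3)
        self.term_rng = _rng(config, 4)
        self.chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
        self.cursor = {c: 5000 for c in self.chrom_names}
        self.claimed = {
            c: np.zeros(config.chrom_length, dtype=bool) for c in self.chrom_names
        }
        self.genome: dict[str, np.ndarray] = {}
        self.loci: dict[str, _Locus] = {}
        self.order: list[str] = []

    # -- placement ---------------------------------------------------------

    def _next_chrom(self) -> str:
        return min(self.chrom_names, key=lambda c: (self.cursor[c], c))

    def _claim(self, chrom: str, exons: list[GenomicInterval]) -> tuple[np.ndarray, np.ndarray]:
        idx = np.concatenate([np.arange(e.start - 1, e.end) for e in exons])
        owned = ~self.claimed[chrom][idx]
        self.claimed[chrom][idx] = True
        return idx, owned

    def _place_intergenic(
        self, tid: str, gid: str, cls: str, strand: str, n_exons: int, length: int
    ) -> None:
        rng = self.place_rng
        chrom = self._next_chrom()
        gap = int(rng.integers(2000, 6000))
        start = self.cursor[chrom] + gap
        exon_lens = _split_length(rng, length, n_exons, min_len=30)
        intron_lens = [int(rng.integers(60, 1200)) for _ in range(n_exons - 1)]
        exons = _exon_intervals(chrom, start, strand, exon_lens, intron_lens)
        end = exons[-1].end
        if end > self.cfg.chrom_length - 5000:
            raise ValueError(
                f"chromosome {chrom} too short to place {tid}; "
                "increase chrom_length or reduce population sizes"
            )
        self.cursor[chrom] = end
        t = TranscriptModel.from_exons(tid, gid, exons, "unknown")
        idx, owned = self._claim(chrom, exons)
        self.loci[tid] = _Locus(t, cls, idx, owned)
        self.order.append(tid)

    def _place_attached(
        self, tid: str, gid: str, cls: str, host_id: str, n_exons: int, length: int
    ) -> None:
        """Place a transcript overlapping its host mRNA's rightmost exon."""
        rng = self.place_rng
        host = self.loci[host_id].transcript
        chrom = host.interval.chrom
        host_last = host.exons[-1]
        strand = (
            host.interval.strand
            if cls == "coding_overlap"
            else ("-" if host.interval.strand == "+" else "+")
        )
        exon_lens = _split_length(rng, length, n_exons, min_len=60)
        ov = int(min(rng.integers(30, 80), host_last.length - 2, exon_lens[0] - 10))
        ov = max(ov, 1)
        start = host_last.end - ov + 1
        intron_lens = [int(rng.integers(60, 1200)) for _ in range(n_exons - 1)]
        exons = _exon_intervals(chrom, start, strand, exon_lens, intron_lens)
        end = exons[-1].end
        if end > self.cfg.chrom_length - 5000:
            raise ValueError(
                f"chromosome {chrom} too short to place {tid}; increase chrom_length"
            )
        self.cursor[chrom] = max(self.cursor[chrom], end)
        t = TranscriptModel.from_exons(tid, gid, exons, "unknown")
        idx, owned = self._claim(chrom, exons)
        self.loci[tid] = _Locus(t, cls, idx, owned, host=host_id)
        self.order.append(tid)

    # -- sequence handling -------------------------------------------------

    def _fill_genome(self) -> None:
        for c in self.chrom_names:
            self.genome[c] = BASES[
                self.seq_rng.integers(0, 4, self.cfg.chrom_length)
            ].copy()

    def extract(self, tid: str) -> str:
        loc = self.loci[tid]
        arr = self.genome[loc.transcript.interval.chrom][loc.all_idx]
        if loc.transcript.interval.strand == "-":
            arr = _revcomp_arr(arr)
        return arr.tobytes().decode()

    def embed(self, tid: str, seq: str) -> None:
        """Write a transcript sequence into the genome (owned bases only)."""
        loc = self.loci[tid]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) != len(loc.all_idx):
            raise ValueError(f"{tid}: sequence length does not match exon structure")
        if loc.transcript.interval.strand == "-":
            arr = _revcomp_arr(arr)
        chrom = loc.transcript.interval.chrom
        self.genome[chrom][loc.all_idx[loc.owned]] = arr[loc.owned]

    def materialize_noncoding(self, tid: str, orf_min: int, orf_max: int) -> str:
        """Rejection-sample owned bases until the mature ORF fits [min, max]."""
        loc = self.loci[tid]
        n_owned = int(loc.owned.sum())
        for attempt in range(500):
            rand = BASES[self.seq_rng.integers(0, 4, n_owned)]
            chrom = loc.transcript.interval.chrom
            self.genome[chrom][loc.all_idx[loc.owned]] = rand
            seq = self.extract(tid)
            if orf_min == 0:
                if longest_orf(seq)[0] <= orf_max:
                    return seq
            else:
                seq = self._implant_orf(seq, orf_min, orf_max)
                orf = longest_orf(seq)[0]
                if orf_min <= orf <= orf_max and orf < 0.5 * len(seq) and orf < 300:
                    self.embed(tid, seq)
                    return seq
        raise RuntimeError(f"could not generate non-coding sequence for {tid}")

    def _implant_orf(self, seq: str, orf_min: int, orf_max: int) -> str:
        rng = self.seq_rng
        n_codons = int(rng.integers(orf_min // 3 + 1, orf_max // 3))
        orf = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
        pos = int(rng.integers(0, len(seq) - len(orf) + 1))
        return seq[:pos] + orf + seq[pos + len(orf) :]

    def make_mrna_seq(self, length: int, rng: np.random.Generator) -> tuple[str, int]:
        """(sequence, orf_end): explicit long ORF with a >=60 nt 3' UTR."""
        utr3 = max(60, int(rng.integers(60, max(61, length // 5))))
        utr5 = int(rng.integers(10, max(11, length // 10)))
        orf_nt = length - utr5 - utr3
        orf_nt -= orf_nt % 3
        utr3 = length - utr5 - orf_nt
        n_codons = orf_nt // 3
        orf = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
        flank = BASES[rng.integers(0, 4, utr5 + utr3)].tobytes().decode()
        seq = flank[:utr5] + orf + flank[utr5:]
        return seq, utr5 + orf_nt


# ---------------------------------------------------------------------------
# straight-line fate audit (expression-independent rules + planted means)

def _audit_fate(
    loc: _Locus,
    seq: str,
    coding_exons: list[GenomicInterval],
    base_mean: float,
) -> str:
    t = loc.transcript
    if t.interval.strand not in ("+", "-"):
        return "strand_certain"
    if t.n_exons < 2:
        return "exon_count"
    if t.length < 200:
        return "min_length"
    for ex in t.exons:
        for ce in coding_exons:
            if ex.strand == ce.strand and ex.overlaps(ce):
                return "annotation_overlap"
    if base_mean <= 0:
        return "min_fpkm"
    orf = longest_orf(seq)[0]
    if orf >= 300 or (orf >= 200 and orf >= 0.5 * len(seq)):
        return "noncoding"
    return "pass"


# ---------------------------------------------------------------------------
# public operations

def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Build the full synthetic dataset (deterministic for a fixed seed)."""
    config.validate()
    b = _Builder(config)
    cfg = config

    n_linc = round(cfg.n_lncrna * cfg.lincrna_fraction)
    n_lncnat = cfg.n_lncrna - n_linc

    mrna_ids = [f"mRNA_{i + 1:04d}" for i in range(cfg.n_mrna)]
    linc_ids = [f"LNC_{i + 1:04d}" for i in range(n_linc)]
    nat_ids = [f"NAT_{i + 1:04d}" for i in range(n_lncnat)]
    cont_ids = {
        "strand_uncertain": [f"CONT_strand_{i + 1:03d}" for i in range(cfg.n_strand_uncertain)],
        "single_exon_artifact": [f"CONT_monoex_{i + 1:03d}" for i in range(cfg.n_single_exon)],
        "short_fragment": [f"CONT_short_{i + 1:03d}" for i in range(cfg.n_short_fragment)],
        "coding_overlap": [f"CONT_senseov_{i + 1:03d}" for i in range(cfg.n_coding_overlap)],
        "low_expression_artifact": [f"CONT_lowexp_{i + 1:03d}" for i in range(cfg.n_low_expression)],
        "coding_contaminant": [f"CONT_coding_{i + 1:03d}" for i in range(cfg.n_coding_contaminant)],
    }

    rngp = b.place_rng

    # assign hosts for attached transcripts up front so each attachment can
    # be placed immediately after its host (the extension region past the
    # host end must still be unoccupied)
    hosts = [mrna_ids[i] for i in rngp.permutation(cfg.n_mrna)] if cfg.n_mrna else []
    attached_by_host: dict[str, tuple[str, str]] = {}
    for tid, host in zip(nat_ids, hosts[:n_lncnat]):
        attached_by_host[host] = ("lncNAT", tid)
    for tid, host in zip(
        cont_ids["coding_overlap"], hosts[n_lncnat : n_lncnat + cfg.n_coding_overlap]
    ):
        attached_by_host[host] = ("coding_overlap", tid)

    # independent (intergenic) loci, placed in a shuffled order
    plan: list[tuple[str, str]] = [("mRNA", t) for t in mrna_ids]
    plan += [("lincRNA", t) for t in linc_ids]
    for cls in ("strand_uncertain", "single_exon_artifact", "short_fragment",
                "low_expression_artifact", "coding_contaminant"):
        plan += [(cls, t) for t in cont_ids[cls]]
    plan = [plan[i] for i in rngp.permutation(len(plan))]

    for cls, tid in plan:
        strand = str(rngp.choice(["+", "-"]))
        if cls == "mRNA":
            k = int(rngp.integers(cfg.mrna_exon_range[0], cfg.mrna_exon_range[1] + 1))
            L = int(rngp.integers(*cfg.mrna_length_range))
        elif cls == "lincRNA":
            k = int(rngp.integers(cfg.lnc_exon_range[0], cfg.lnc_exon_range[1] + 1))
            L = int(rngp.integers(*cfg.lnc_length_range))
        elif cls == "strand_uncertain":
            strand = "."
            k, L = 2, int(rngp.integers(300, 900))
        elif cls == "single_exon_artifact":
            k, L = 1, int(rngp.integers(250, 800))
        elif cls == "short_fragment":
            k, L = 2, int(rngp.integers(80, 199))
        elif cls == "low_expression_artifact":
            k, L = 2, int(rngp.integers(300, 900))
        else:  # coding_contaminant
            k, L = 2, int(rngp.integers(700, 1500))
        gid = f"G_{tid}"
        b._place_intergenic(tid, gid, cls, strand, k, L)
        if cls == "mRNA" and tid in attached_by_host:
            acls, atid = attached_by_host[tid]
            if acls == "lncNAT":
                ak = int(rngp.integers(cfg.lnc_exon_range[0], cfg.lnc_exon_range[1] + 1))
                aL = int(
                    rngp.integers(
                        max(cfg.lnc_length_range[0], 60 * ak + 40),
                        cfg.lnc_length_range[1],
                    )
                )
            else:
                ak, aL = 2, int(rngp.integers(300, 900))
            b._place_attached(atid, f"G_{atid}", acls, tid, ak, aL)

    # -- sequences ---------------------------------------------------------
    b._fill_genome()
    seqs: dict[str, str] = {}
    rngs = b.seq_rng

    for tid in mrna_ids:
        seq, _ = b.make_mrna_seq(b.loci[tid].transcript.length, rngs)
        b.embed(tid, seq)
        seqs[tid] = seq
    orf_ends = {}
    for tid in mrna_ids:  # recompute ORF end from the committed sequence
        orf_ends[tid] = longest_orf(seqs[tid])[3] or 0
    for tid in cont_ids["coding_contaminant"]:
        L = b.loci[tid].transcript.length
        seq, _ = b.make_mrna_seq(L, rngs)
        b.embed(tid, seq)
        seqs[tid] = seq

    n_long = round(n_linc * cfg.lnc_long_orf_fraction)
    long_orf_ids = set(
        tid for tid in np.array(linc_ids)[
            b.seq_rng.permutation(n_linc)[:n_long]
        ]
        if b.loci[tid].transcript.length >= 600
    )
    for tid in linc_ids:
        if tid in long_orf_ids:
            seqs[tid] = b.materialize_noncoding(tid, cfg.lnc_orf_cap + 1, 280)
        else:
            seqs[tid] = b.materialize_noncoding(tid, 0, cfg.lnc_orf_cap)
    for cls in ("strand_uncertain", "single_exon_artifact", "short_fragment",
                "low_expression_artifact"):
        for tid in cont_ids[cls]:
            seqs[tid] = b.materialize_noncoding(tid, 0, cfg.lnc_orf_cap)
    for tid in nat_ids:
        seqs[tid] = b.materialize_noncoding(tid, 0, cfg.lnc_orf_cap)
    for tid in cont_ids["coding_overlap"]:
        seqs[tid] = b.extract(tid)  # sequence content irrelevant: removed at round 3

    # -- expression design: base means and planted DE ----------------------
    rngd = b.de_rng
    de = cfg.de_config

    def _log_uniform(rng, lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    base_mean: dict[str, float] = {}
    for tid in mrna_ids:
        base_mean[tid] = float(_log_uniform(rngd, *cfg.mrna_mean_range, 1)[0])
    lnc_all = linc_ids + nat_ids
    for tid in lnc_all:
        base_mean[tid] = float(_log_uniform(rngd, *cfg.lnc_mean_range, 1)[0])
    for cls, ids in cont_ids.items():
        for tid in ids:
            base_mean[tid] = (
                0.0
                if cls == "low_expression_artifact"
                else float(_log_uniform(rngd, 50.0, 500.0, 1)[0])
            )

    lfc: dict[str, float] = {t: 0.0 for t in base_mean}
    direction: dict[str, str] = {t: "ns" for t in base_mean}
    lnc_perm = [lnc_all[i] for i in rngd.permutation(len(lnc_all))]
    up_lnc = lnc_perm[: de.n_up_lnc]
    down_lnc = lnc_perm[de.n_up_lnc : de.n_up_lnc + de.n_down_lnc]
    mrna_perm = [mrna_ids[i] for i in rngd.permutation(cfg.n_mrna)]
    up_mrna = mrna_perm[: de.n_up_mrna]
    down_mrna = mrna_perm[de.n_up_mrna : de.n_up_mrna + de.n_down_mrna]
    for tid in up_lnc + up_mrna:
        lfc[tid] = float(rngd.uniform(*de.lfc_range))
        direction[tid] = "up"
    for tid in down_lnc + down_mrna:
        lfc[tid] = -float(rngd.uniform(*de.lfc_range))
        direction[tid] = "down"

    # -- miRNAs and planted binding sites ----------------------------------
    rngm = b.site_rng
    mirnas = {
        f"miR_{i + 1:03d}": "".join(
            "ACGU"[j] for j in rngm.integers(0, 4, cfg.mirna_length)
        )
        for i in range(cfg.n_mirna)
    }
    site_rows: list[dict] = []
    if cfg.n_planted_triplets > 0:
        # host mRNAs share bases with their attached transcript, so sites are
        # planted only in mRNAs that fully own their sequence
        site_lnc_pool = [t for t in linc_ids if direction[t] == "down"]
        site_mrna_pool = [
            t
            for t in down_mrna
            if t not in attached_by_host
            and len(seqs[t]) - orf_ends[t] > cfg.mirna_length + 10
        ]
        if (
            len(site_lnc_pool) < cfg.n_planted_triplets
            or len(site_mrna_pool) < cfg.n_planted_triplets
        ):
            raise ValueError("not enough down-regulated transcripts to plant triplets")
        mir_ids = sorted(mirnas)
        used_sites: dict[str, list[tuple[int, int]]] = {}
        for i in range(cfg.n_planted_triplets):
            mid = mir_ids[i % len(mir_ids)]
            lnc = site_lnc_pool[i]
            mrna = site_mrna_pool[i]
            site_dna = dna(_revcomp(mirnas[mid].replace("U", "T")))
            for target, kind in ((lnc, "lncRNA"), (mrna, "mRNA")):
                pos = _plant_site(
                    b, seqs, target, site_dna, kind, orf_ends, used_sites, rngm, cfg
                )
                site_rows.append(
                    {
                        "mirna_id": mid,
                        "target_id": target,
                        "target_kind": kind,
                        "site_start": pos + 1,
                        "site_type": "perfect",
                    }
                )

    # -- reference annotation ----------------------------------------------
    annotation: list[TranscriptModel] = []
    for tid in mrna_ids:
        t = b.loci[tid].transcript
        annotation.append(replace(t, biotype="protein_coding"))
    n_ann = round(cfg.n_lncrna * cfg.annotated_lnc_fraction)
    ann_lnc_ids = [lnc_all[i] for i in sorted(rngd.permutation(len(lnc_all))[:n_ann])]
    for tid in ann_lnc_ids:
        t = b.loci[tid].transcript
        annotation.append(
            TranscriptModel(
                f"ANN_{tid}", f"ANNG_{tid}", t.interval, list(t.exons),
                "lncRNA_annotated",
            )
        )

    candidate_ids = lnc_all + [t for ids in cont_ids.values() for t in ids]
    candidates = [b.loci[t].transcript for t in candidate_ids]

    # -- fate audit (straight-line application of the cascade rules) -------
    coding_exons = [ex for t in annotation if t.biotype == "protein_coding" for ex in t.exons]
    rows = []
    for tid in mrna_ids:
        rows.append(
            dict(transcript_id=tid, biotype="mRNA", role="reference",
                 gene_id=f"G_{tid}", chrom=b.loci[tid].transcript.interval.chrom,
                 de=direction[tid], log2fc=lfc[tid], base_mean=base_mean[tid],
                 fate="reference", annotated="yes")
        )
    for tid in candidate_ids:
        loc = b.loci[tid]
        cls = {"lincRNA": "lincRNA", "lncNAT": "lncNAT"}.get(loc.cls, loc.cls)
        fate = _audit_fate(loc, seqs[tid], coding_exons, base_mean[tid])
        if cls in ("lincRNA", "lncNAT") and fate != "pass":
            # a planted lncRNA must never be removed by its own construction
            raise AssertionError(f"planted lncRNA {tid} would be removed at {fate}")
        rows.append(
            dict(transcript_id=tid, biotype=cls, role="candidate",
                 gene_id=f"G_{tid}", chrom=loc.transcript.interval.chrom,
                 de=direction[tid], log2fc=lfc[tid], base_mean=base_mean[tid],
                 fate=fate, annotated="yes" if tid in ann_lnc_ids else "no")
        )
    truth_cols = [
        "transcript_id", "biotype", "role", "gene_id", "chrom", "de",
        "log2fc", "base_mean", "fate", "annotated",
    ]
    truth_df = pd.DataFrame(rows, columns=truth_cols).set_index("transcript_id")
    sites_df = pd.DataFrame(
        site_rows,
        columns=["mirna_id", "target_id", "target_kind", "site_start", "site_type"],
    )
    truth = SyntheticTruth(truth_df, sites_df)

    # -- term map -----------------------------------------------------------
    terms = _make_terms(b, cfg, truth, mrna_ids, down_lnc, down_mrna)

    counts = simulate_counts(truth, cfg)

    genome = {c: b.genome[c].tobytes().decode() for c in b.chrom_names}
    all_seqs = {tid: seqs[tid] for tid in mrna_ids + candidate_ids}
    return SyntheticDataset(
        cfg, annotation, candidates, genome, all_seqs, mirnas, counts, terms, truth
    )


def _plant_site(
    b: _Builder,
    seqs: dict[str, str],
    target: str,
    site_dna: str,
    kind: str,
    orf_ends: dict[str, int],
    used: dict[str, list[tuple[int, int]]],
    rng: np.random.Generator,
    cfg: SyntheticConfig,
) -> int:
    """Write a binding site into a transcript; returns 0-based position."""
    seq = seqs[target]
    L = len(site_dna)
    lo = orf_ends.get(target, 0) if kind == "mRNA" else 0
    hi = len(seq) - L
    if hi < lo:
        raise ValueError(f"{target}: transcript too short for a binding site")
    for _ in range(100):
        pos = int(rng.integers(lo, hi + 1))
        if any(pos < e and s < pos + L for s, e in used.get(target, [])):
            continue
        cand = seq[:pos] + site_dna + seq[pos + L :]
        if kind == "lncRNA":
            # the site must not turn the lncRNA coding (cascade round 5)
            orf = longest_orf(cand)[0]
            if orf >= 300 or (orf >= 200 and orf >= 0.5 * len(cand)):
                continue
        seqs[target] = cand
        b.embed(target, cand)
        used.setdefault(target, []).append((pos, pos + L))
        return pos
    raise RuntimeError(f"could not place a non-overlapping site in {target}")


def _make_terms(
    b: _Builder,
    cfg: SyntheticConfig,
    truth: SyntheticTruth,
    mrna_ids: list[str],
    down_lnc: list[str],
    down_mrna: list[str],
) -> pd.DataFrame:
    """Gene -> pathway table with one planted enriched pathway."""
    rng = b.term_rng
    rows: list[dict] = []
    if cfg.n_terms == 0 or not mrna_ids:
        return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])

    # genes of the positive-control pathway: down mRNAs co-localized with a
    # down lncRNA (guaranteed enrichment among down-DEL targets)
    down_lnc_ivs = [b.loci[t].transcript.interval for t in down_lnc]
    eligible = []
    for tid in down_mrna:
        iv = b.loci[tid].transcript.interval
        for lv in down_lnc_ivs:
            d = iv.distance(lv)
            if d is not None and d <= cfg.cis_window:
                eligible.append(tid)
                break
    n_in = min(cfg.enriched_term_overlap, len(eligible))
    chosen = [eligible[i] for i in sorted(rng.permutation(len(eligible))[:n_in])]
    others = [t for t in mrna_ids if t not in set(chosen) and truth.transcripts.loc[t, "de"] == "ns"]
    n_out = min(cfg.enriched_term_size - n_in, len(others))
    filler = [others[i] for i in sorted(rng.permutation(len(others))[:n_out])]
    for g in chosen + filler:
        rows.append({"gene_id": f"G_{g}", "term_id": "T001", "term_name": "pathway_001"})

    for k in range(2, cfg.n_terms + 1):
        size = int(rng.integers(10, 40))
        members = [mrna_ids[i] for i in sorted(rng.permutation(len(mrna_ids))[:size])]
        for g in members:
            rows.append(
                {"gene_id": f"G_{g}", "term_id": f"T{k:03d}", "term_name": f"pathway_{k:03d}"}
            )
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


def simulate_counts(truth: SyntheticTruth, config: SyntheticConfig) -> ExpressionMatrix:
    """NB(mu, alpha) counts with planted fold changes in the aged condition.

    mu_is = base_mean_i * 2^log2fc_i (aged samples only) * library_factor_s;
    library factors vary less than 2x across samples. Deterministic for a
    fixed config seed.
    """
    if config.nb_dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = _rng(config, 5)
    n_rep = config.n_replicates
    samples = [f"S50_{i + 1}" for i in range(n_rep)] + [
        f"S96_{i + 1}" for i in range(n_rep)
    ]
    design = {s: ("aged" if s.startswith("S50") else "new") for s in samples}
    lib = rng.uniform(*config.library_factor_range, size=2 * n_rep)

    t = truth.transcripts
    base = t["base_mean"].to_numpy(dtype=float)
    lfc = t["log2fc"].to_numpy(dtype=float)
    mu_aged = base * 2.0**lfc
    mu_new = base
    mu = np.concatenate(
        [np.outer(mu_aged, lib[:n_rep]), np.outer(mu_new, lib[n_rep:])], axis=1
    )
    alpha = config.nb_dispersion
    if alpha < 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=t.index, columns=samples)
    return ExpressionMatrix(df, design, kind="counts")


def export_dataset(
    dataset: SyntheticDataset, directory: str | Path, overwrite: bool = False
) -> dict[str, Path]:
    """Write the dataset as plain-text files; re-reading reproduces it."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)

    paths = {name: directory / name for name in (
        "annotation.gtf", "candidates.gtf", "genome.fa", "transcripts.fa",
        "counts.tsv", "design.tsv", "mirnas.fa", "terms.tsv", "truth.tsv",
    )}
    sio.write_gtf(dataset.annotation, paths["annotation.gtf"])
    sio.write_gtf(dataset.candidates, paths["candidates.gtf"])
    sio.write_fasta(dataset.genome, paths["genome.fa"])
    sio.write_fasta(dataset.transcript_seqs, paths["transcripts.fa"])
    sio.write_expression_table(dataset.counts, paths["counts.tsv"], paths["design.tsv"])
    sio.write_fasta(dataset.mirnas, paths["mirnas.fa"])
    dataset.terms.to_csv(paths["terms.tsv"], sep="\t", index=False)

    t = dataset.truth.transcripts.reset_index()
    t.insert(0, "kind", "transcript")
    s = dataset.truth.sites.copy()
    s.insert(0, "kind", "site")
    pd.concat([t, s], ignore_index=True).to_csv(
        paths["truth.tsv"], sep="\t", index=False
    )
    return paths


def load_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t")
    t = df[df["kind"] == "transcript"].dropna(axis=1, how="all").drop(columns="kind")
    s = df[df["kind"] == "site"].dropna(axis=1, how="all").drop(columns="kind")
    t = t.set_index("transcript_id")
    if len(s):
        s = s.astype({"site_start": int})
    else:
        s = pd.DataFrame(
            columns=["mirna_id", "target_id", "target_kind", "site_start", "site_type"]
        )
    return SyntheticTruth(t, s.reset_index(drop=True))
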