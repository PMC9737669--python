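"""Readers and writers for the formats the pipeline touches.

GTF (Ensembl-dialect attributes), FASTA, tab-separated tables with a header
row, and three-column network edge lists. Round-trips are lossless for every
field downstream stages read. Sequences are stored in the DNA alphabet; the
miRNA scanner converts to RNA on entry.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from gffutils.iterators import DataIterator

from .models import ExpressionMatrix, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

_KNOWN_FEATURES = {"transcript", "exon", "gene"}

# GTF transcript_biotype attribute values mapped onto the internal biotypes
_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA_annotated",
    "lncRNA_annotated": "lncRNA_annotated",
}


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF file into TranscriptModels.

    Exon records are grouped by ``transcript_id`` and sorted by start; a
    transcript feature is optional (the span is synthesized from its exons
    when absent, and a note is logged). Unknown feature types are ignored,
    logged once per type.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0 or not _has_feature_lines(path):
        return []

    exons: "OrderedDict[str, list[GenomicInterval]]" = OrderedDict()
    meta: dict[str, dict[str, str]] = {}
    has_transcript_feature: set[str] = set()
    unknown_logged: set[str] = set()

    for lineno, feat in enumerate(DataIterator(str(path)), start=1):
        if feat.featuretype not in _KNOWN_FEATURES:
            if feat.featuretype not in unknown_logged:
                logger.info(
                    "ignoring GTF feature type %r (%s)", feat.featuretype, path
                )
                unknown_logged.add(feat.featuretype)
            continue
        if feat.featuretype == "gene":
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except (KeyError, IndexError) as exc:
            raise ValueError(
                f"{path}: malformed attribute string near line {lineno}: "
                f"missing transcript_id/gene_id ({exc})"
            ) from None
        biotype_attr = feat.attributes.get("transcript_biotype", ["unknown"])[0]
        meta.setdefault(
            tid,
            {
                "gene_id": gid,
                "biotype": _BIOTYPE_MAP.get(biotype_attr, "unknown"),
            },
        )
        if feat.featuretype == "transcript":
            has_transcript_feature.add(tid)
        elif feat.featuretype == "exon":
            exons.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
            )

    out: list[TranscriptModel] = []
    for tid, exs in exons.items():
        if tid not in has_transcript_feature:
            logger.info("transcript %s synthesized from exon span", tid)
        out.append(
            TranscriptModel.from_exons(
                tid, meta[tid]["gene_id"], exs, meta[tid]["biotype"]
            )
        )
    return out


def _has_feature_lines(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return True
    return False


_REVERSE_BIOTYPE = {"protein_coding": "protein_coding", "lncRNA_annotated": "lncRNA"}


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF (one transcript line + one line per exon)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#!seedlnc GTF export\n")
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.biotype != "unknown":
                attrs += f' transcript_biotype "{_REVERSE_BIOTYPE[t.biotype]}";'
            iv = t.interval
            fh.write(
                f"{iv.chrom}\tseedlnc\ttranscript\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for ex in t.exons:
                fh.write(
                    f"{ex.chrom}\tseedlnc\texon\t{ex.start}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


def read_fasta(path: str | Path, alphabet: str = "dna") -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence mapping.

    alphabet="dna" normalizes U->T; alphabet="rna" normalizes T->U (used for
    mature miRNA inputs). Duplicate ids and empty records are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if alphabet not in ("dna", "rna"):
        raise ValueError("alphabet must be 'dna' or 'rna'")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        if alphabet == "dna":
            seq = seq.replace("U", "T")
        else:
            seq = seq.replace("T", "U")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_expression_table(
    path: str | Path, design_path: str | Path, kind: str = "counts"
) -> ExpressionMatrix:
    """Read a transcripts x samples TSV plus a (sample, condition) design TSV."""
    path, design_path = Path(path), Path(design_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.columns[~df.apply(pd.api.types.is_numeric_dtype)]
    if len(bad):
        col = bad[0]
        row = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
        raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    design_df = pd.read_csv(design_path, sep="\t")
    if not {"sample", "condition"} <= set(design_df.columns):
        raise ValueError(f"{design_path}: needs 'sample' and 'condition' columns")
    design = dict(zip(design_df["sample"], design_df["condition"]))
    missing = [s for s in df.columns if s not in design]
    if missing:
        raise ValueError(f"samples in table absent from design: {missing}")
    return ExpressionMatrix(df, design, kind=kind)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, design_path: str | Path | None = None
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="transcript_id")
    if design_path is not None:
        pd.DataFrame(
            {
                "sample": matrix.sample_ids,
                "condition": [matrix.design[s] for s in matrix.sample_ids],
            }
        ).to_csv(design_path, sep="\t", index=False)


def write_edge_list(
    edges: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    """Write (source, interaction, target) edges as a deterministic TSV.

    Rows are sorted by (source, target, interaction) so identical edge sets
    always produce byte-identical files, whatever order they arrive in.
    """
    rows = sorted(set(edges), key=lambda e: (e[0], e[2], e[1]))
    with open(path, "w") as fh:
        fh.write("source\tinteraction\ttarget\n")
        for src, rel, dst in rows:
            fh.write(f"{src}\t{rel}\t{dst}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df[["source", "interaction", "target"]].itertuples(index=False)]
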