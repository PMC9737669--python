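from __future__ import annotations

import numpy as np
import pytest

from seedlnc import (
    GenomicInterval,
    PipelineConfig,
    SyntheticConfig,
    TranscriptModel,
    generate_dataset,
    run_pipeline,
)

FIXTURE_SEED = 11


def make_transcript(
    tid: str,
    exons: list[tuple[int, int]],
    chrom: str = "chr1",
    strand: str = "+",
    gene_id: str | None = None,
    biotype: str = "unknown",
) -> TranscriptModel:
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    return TranscriptModel.from_exons(tid, gene_id or f"G_{tid}", ivs, biotype)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (two conditions x 3 replicates)."""
    return generate_dataset(SyntheticConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A full pipeline run on the default synthetic study."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(outdir=str(outdir), seed=FIXTURE_SEED)
    return run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(FIXTURE_SEED)
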