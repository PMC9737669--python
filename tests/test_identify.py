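from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seedlnc import (
    ExpressionMatrix,
    characterize,
    classify_lncrna,
    coding_potential,
    filter_cascade,
    longest_orf,
)

from conftest import make_transcript
from helpers import brute_force_longest_orf, straightline_cascade


class TestLongestOrf:
    def test_no_start_codon(self):
        assert longest_orf("CCCCCC")[0] == 0

    def test_minimal_orf(self):
        length, frame, start, end = longest_orf("ATGTAA")
        assert (length, frame, start, end) == (6, 0, 1, 6)

    def test_too_short(self):
        assert longest_orf("ATGTA")[0] == 0

    def test_orf_in_other_frame(self):
        # shifted by one base: frame 1
        length, frame, start, end = longest_orf("CATGAAATAG")
        assert length == 9 and frame == 1 and start == 2 and end == 10

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 1000))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            assert longest_orf(seq)[0] == brute_force_longest_orf(seq)

    def test_orf_without_stop_does_not_count(self):
        assert longest_orf("ATGAAAAAA")[0] == 0


class TestCodingPotential:
    def test_no_orf_scores_zero_noncoding(self):
        cp = coding_potential("C" * 1000)
        assert cp.score == 0 and not cp.is_coding and cp.longest_orf_nt == 0

    def test_long_orf_forces_coding(self):
        seq = "ATG" + "GCT" * 298 + "TAA"
        cp = coding_potential(seq + "C" * 100)
        assert cp.longest_orf_nt == 900
        assert cp.is_coding

    def test_300nt_boundary_inclusive(self):
        orf = "ATG" + "GCT" * 98 + "TAA"  # exactly 300 nt
        assert len(orf) == 300
        cp = coding_potential(orf + "C" * 700)  # coverage 0.3 < 0.5
        assert cp.longest_orf_nt == 300 and cp.is_coding

    def test_midsize_orf_needs_coverage(self):
        orf = "ATG" + "GCT" * 65 + "TAA"  # 201 nt
        assert coding_potential(orf + "C" * 300).is_coding is False  # cov 0.40
        assert coding_potential(orf + "C" * 100).is_coding is True  # cov 0.67

    def test_score_monotone_in_orf_length(self):
        seqs = ["ATG" + "GCT" * k + "TAA" + "C" * 400 for k in (10, 40, 80)]
        scores = [coding_potential(s).score for s in seqs]
        assert scores == sorted(scores)


def _cascade_fixture():
    """Six hand-built candidates, one designed to fail each rule."""
    ann_mrna = make_transcript(
        "m1", [(1000, 1400), (2000, 2600)], strand="+", biotype="protein_coding"
    )
    cands = [
        make_transcript("no_strand", [(50_000, 50_300), (51_000, 51_200)], strand="."),
        make_transcript("mono", [(60_000, 60_500)], strand="+"),
        make_transcript("short", [(70_000, 70_080), (71_000, 71_090)], strand="-"),
        make_transcript("overlap", [(2100, 2400), (3000, 3200)], strand="+"),
        make_transcript("silent", [(80_000, 80_300), (81_000, 81_200)], strand="+"),
        make_transcript("coding", [(90_000, 90_500), (91_000, 91_400)], strand="+"),
        make_transcript("clean", [(100_000, 100_300), (101_000, 101_250)], strand="-"),
    ]
    fpkm = pd.DataFrame(
        1.0, index=[t.transcript_id for t in cands], columns=["s1", "s2"]
    )
    fpkm.loc["silent"] = 0.2
    matrix = ExpressionMatrix(fpkm, {"s1": "aged", "s2": "new"}, kind="fpkm")
    coding = {
        t.transcript_id: coding_potential("C" * 400, t.transcript_id) for t in cands
    }
    coding["coding"] = coding_potential("ATG" + "GCT" * 198 + "TAA", "coding")
    return cands, matrix, [ann_mrna], coding


class TestFilterCascade:
    def test_empty_input(self):
        _, matrix, ann, _ = _cascade_fixture()
        records, report = filter_cascade([], matrix, ann, {})
        assert records == []
        assert (report.to_frame()["n_input"] == 0).all()

    def test_each_rule_removes_its_designed_candidate(self):
        cands, matrix, ann, coding = _cascade_fixture()
        records, report = filter_cascade(cands, matrix, ann, coding)
        assert [r.transcript.transcript_id for r in records] == ["clean"]
        removed = {s.name: s.removed_ids for s in report.steps}
        assert removed["strand_certain"] == ["no_strand"]
        assert removed["exon_count"] == ["mono"]
        assert removed["min_length"] == ["short"]
        assert removed["annotation_overlap"] == ["overlap"]
        assert removed["min_fpkm"] == ["silent"]
        assert removed["noncoding"] == ["coding"]
        report.validate()

    def test_counts_telescope(self):
        cands, matrix, ann, coding = _cascade_fixture()
        _, report = filter_cascade(cands, matrix, ann, coding)
        df = report.to_frame()
        assert (df["n_surviving"].to_numpy()[:-1] == df["n_input"].to_numpy()[1:]).all()

    def test_order_invariance(self, rng):
        cands, matrix, ann, coding = _cascade_fixture()
        records1, _ = filter_cascade(cands, matrix, ann, coding)
        shuffled = [cands[i] for i in rng.permutation(len(cands))]
        records2, _ = filter_cascade(shuffled, matrix, ann, coding)
        ids1 = {r.transcript.transcript_id for r in records1}
        ids2 = {r.transcript.transcript_id for r in records2}
        assert ids1 == ids2

    def test_missing_fpkm_and_coding_raise(self):
        cands, matrix, ann, coding = _cascade_fixture()
        with pytest.raises(KeyError, match="missing from FPKM"):
            filter_cascade(cands, matrix.subset(["mono"]), ann, coding)
        del coding["clean"]
        with pytest.raises(KeyError, match="coding score"):
            filter_cascade(cands, matrix, ann, coding)

    def test_survivors_match_planted_truth(self, default_dataset):
        """On the synthetic study, survivors equal the planted pass set."""
        ds = default_dataset
        from seedlnc.de import compute_fpkm

        lengths = {t.transcript_id: t.length for t in ds.candidates + ds.annotation}
        fpkm = compute_fpkm(ds.counts, lengths)
        coding = {
            t.transcript_id: coding_potential(
                ds.transcript_seqs[t.transcript_id], t.transcript_id
            )
            for t in ds.candidates
        }
        records, report = filter_cascade(ds.candidates, fpkm, ds.annotation, coding)
        assert {r.transcript.transcript_id for r in records} == ds.truth.pass_ids()
        # annotated lncRNAs carry annotated status
        ann = {
            r.transcript.transcript_id
            for r in records
            if r.status == "annotated"
        }
        truth_ann = set(
            ds.truth.transcripts.index[
                (ds.truth.transcripts["annotated"] == "yes")
                & (ds.truth.transcripts["role"] == "candidate")
            ]
        )
        assert ann == truth_ann

    def test_matches_straightline_reimplementation(self, default_dataset):
        ds = default_dataset
        from seedlnc.de import compute_fpkm

        lengths = {t.transcript_id: t.length for t in ds.candidates + ds.annotation}
        fpkm = compute_fpkm(ds.counts, lengths)
        coding = {
            t.transcript_id: coding_potential(
                ds.transcript_seqs[t.transcript_id], t.transcript_id
            )
            for t in ds.candidates
        }
        records, _ = filter_cascade(ds.candidates, fpkm, ds.annotation, coding)
        expected = straightline_cascade(
            ds.candidates, fpkm.values, ds.annotation, coding
        )
        assert {r.transcript.transcript_id for r in records} == expected


class TestClassify:
    def _genes(self):
        return [
            make_transcript(
                "g1", [(10_000, 10_500), (12_000, 12_800)], strand="+",
                biotype="protein_coding",
            )
        ]

    def test_distant_transcript_is_lincRNA(self):
        t = make_transcript("t", [(40_000, 40_300), (41_000, 41_200)], strand="+")
        assert classify_lncrna(t, self._genes()) == "lincRNA"

    def test_antisense_exonic_overlap_is_lncNAT(self):
        t = make_transcript("t", [(10_400, 10_700), (11_000, 11_300)], strand="-")
        assert classify_lncrna(t, self._genes()) == "lncNAT"

    def test_inside_intron_same_strand_is_intronic(self):
        t = make_transcript("t", [(10_600, 10_800), (11_200, 11_500)], strand="+")
        assert classify_lncrna(t, self._genes()) == "intronic"

    def test_span_overlap_without_exonic_is_sense_overlapping(self):
        # first exon in the intron, second past the gene end, same strand
        t = make_transcript("t", [(11_000, 11_400), (13_000, 13_300)], strand="+")
        assert classify_lncrna(t, self._genes()) == "sense_overlapping"

    def test_every_record_satisfies_its_class_invariant(self, pipeline_run):
        """Direct coordinate re-check of each emitted record's class."""
        coding = [
            t for t in pipeline_run["annotation"] if t.biotype == "protein_coding"
        ]
        for r in pipeline_run["records"]:
            t = r.transcript
            if r.cls == "lncNAT":
                assert any(
                    g.interval.strand != t.interval.strand and t.exonic_overlap(g)
                    for g in coding
                )
            elif r.cls == "lincRNA":
                assert not any(g.interval.overlaps(t.interval) for g in coding)
            elif r.cls == "intronic":
                assert any(
                    any(i.contains(t.interval) for i in g.introns()) for g in coding
                )
            else:
                assert any(
                    g.interval.overlaps(t.interval) and not t.exonic_overlap(g)
                    for g in coding
                )


class TestCharacterize:
    def test_single_transcript_mass_in_one_bin(self):
        t = make_transcript("t", [(100, 249), (400, 549)], strand="+")
        seqs = {"t": "C" * 300}
        tables = characterize([t], [], seqs)
        assert tables["exon_count"]["lncRNA"]["2"] == 1.0
        assert tables["transcript_length"]["lncRNA"]["200-400"] == 1.0
        assert tables["orf_length"]["lncRNA"]["0-100"] == 1.0

    def test_proportions_sum_to_one(self, default_dataset):
        ds = default_dataset
        lnc = [
            t
            for t in ds.candidates
            if ds.truth.transcripts.loc[t.transcript_id, "biotype"]
            in ("lincRNA", "lncNAT")
        ]
        mrna = [t for t in ds.annotation if t.biotype == "protein_coding"]
        tables = characterize(lnc, mrna, ds.transcript_seqs)
        for df in tables.values():
            np.testing.assert_allclose(df.sum(axis=0), 1.0, atol=1e-9)

    def test_planted_structure_audit(self, default_dataset):
        """The generated lncRNA population mirrors the study's profile:

        >90% with 2-3 exons and >90% with ORF <= 200 nt.
        """
        ds = default_dataset
        lnc = [
            t
            for t in ds.candidates
            if ds.truth.transcripts.loc[t.transcript_id, "biotype"]
            in ("lincRNA", "lncNAT")
        ]
        mrna = [t for t in ds.annotation if t.biotype == "protein_coding"]
        tables = characterize(lnc, mrna, ds.transcript_seqs)
        exon_mass = tables["exon_count"]["lncRNA"][["2", "3"]].sum()
        assert exon_mass >= 0.9
        orf_mass = tables["orf_length"]["lncRNA"][["0-100", "100-200"]].sum()
        assert orf_mass > 0.9

    def test_empty_population_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            tables = characterize([], [], {})
        assert any("empty" in r.message for r in caplog.records)
        assert (tables["exon_count"]["lncRNA"] == 0).all()
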