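from __future__ import annotations

import numpy as np
import pytest

from seedlnc import build_cerna_network, duplex_score, expectation_score, scan_targets
from seedlnc.cerna import network_edges, scan_all
from seedlnc.models import MiRNATargetHit

from helpers import brute_force_join

RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def perfect_site(mirna: str) -> str:
    """Reverse complement in RNA space: the perfectly pairing site."""
    return "".join(RC[b] for b in reversed(mirna))


def scalar_duplex(mirna: str, site: str) -> float:
    """Independent per-position recomputation of the pseudo-energy."""
    total = 0.0
    for a, b in zip(mirna, reversed(site)):
        if {a, b} == {"G", "C"}:
            total -= 3
        elif {a, b} == {"A", "U"}:
            total -= 2
        elif {a, b} == {"G", "U"}:
            total -= 1
        else:
            total += 1
    return total


class TestDuplexScore:
    def test_perfect_complement_forced_value(self):
        mirna = "G" * 5 + "C" * 5 + "A" * 6 + "U" * 5  # 10 GC + 11 AU pairs
        assert duplex_score(mirna, perfect_site(mirna))[0] == -(10 * 3 + 11 * 2)

    def test_all_mismatch_scores_plus_length(self):
        mirna = "A" * 21
        site = "C" * 21  # A:C never pairs
        energy, mask = duplex_score(mirna, site)
        assert energy == 21.0
        assert mask == "." * 21

    def test_wobble_scoring(self):
        energy, mask = duplex_score("G", "U")
        assert energy == -1.0 and mask == ":"

    def test_matches_independent_recomputation(self, rng):
        for _ in range(200):
            m = "".join("ACGU"[i] for i in rng.integers(0, 4, 21))
            s = "".join("ACGU"[i] for i in rng.integers(0, 4, 21))
            assert duplex_score(m, s)[0] == scalar_duplex(m, s)

    def test_non_rna_rejected(self):
        with pytest.raises(ValueError, match="non-RNA"):
            duplex_score("AXG", "UUU")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            duplex_score("AAA", "UU")


class TestExpectationScore:
    def test_perfect_site_scores_zero(self):
        m = "UGACAGAAGAGAGUGAGCACA"
        assert expectation_score(m, perfect_site(m)) == 0.0

    def test_single_mismatch_in_seed_doubled(self):
        m = "A" * 21
        site = list(perfect_site(m))
        # miRNA position 5 pairs with site position 21 - 5 = 16 (0-based)
        site[21 - 5] = "C"
        assert expectation_score(m, "".join(site)) == 2.0

    def test_wobble_outside_seed_half_point(self):
        m = "G" * 21
        site = list(perfect_site(m))  # all C
        site[21 - 15] = "U"  # G:U at miRNA position 15
        assert expectation_score(m, "".join(site)) == 0.5

    def test_position_one_never_doubled(self):
        m = "A" * 21
        site = list(perfect_site(m))
        site[20] = "C"  # pairs miRNA position 1
        assert expectation_score(m, "".join(site)) == 1.0


class TestScanTargets:
    def test_planted_site_found_at_exact_position(self, rng):
        m = "".join("ACGU"[i] for i in rng.integers(0, 4, 21))
        flank = "".join("ACGU"[i] for i in rng.integers(0, 4, 400))
        target = flank[:100] + perfect_site(m) + flank[100:]
        hits = scan_targets("mi", m, "t", target, "lncRNA")
        assert any(h.site_start == 101 for h in hits)
        best = min(hits, key=lambda h: h.score)
        assert best.site_start == 101
        assert best.score == duplex_score(m, perfect_site(m))[0]

    def test_translation_invariance(self, rng):
        m = "".join("ACGU"[i] for i in rng.integers(0, 4, 21))
        target = "".join("ACGU"[i] for i in rng.integers(0, 4, 300))
        target = target[:50] + perfect_site(m) + target[50:]
        prefix = "".join("ACGU"[i] for i in rng.integers(0, 4, 77))
        h1 = scan_targets("mi", m, "t", target, "lncRNA")
        h2 = scan_targets("mi", m, "t", prefix + target, "lncRNA")
        moved = {(h.site_start + 77, h.score) for h in h1}
        assert moved <= {(h.site_start, h.score) for h in h2}

    def test_determinism(self, rng):
        m = "".join("ACGU"[i] for i in rng.integers(0, 4, 21))
        t = "".join("ACGU"[i] for i in rng.integers(0, 4, 2000))
        assert scan_targets("mi", m, "x", t, "lncRNA") == scan_targets(
            "mi", m, "x", t, "lncRNA"
        )

    def test_short_target_yields_nothing(self):
        assert scan_targets("mi", "A" * 21, "t", "ACGU" * 5, "lncRNA") == []

    def test_kept_hits_do_not_overlap(self, rng):
        m = "".join("ACGU"[i] for i in rng.integers(0, 4, 21))
        t = "".join("ACGU"[i] for i in rng.integers(0, 4, 3000))
        hits = scan_targets("mi", m, "x", t, "lncRNA", energy_cutoff=-10.0)
        starts = sorted(h.site_start for h in hits)
        assert all(b - a >= 21 for a, b in zip(starts, starts[1:]))

    @staticmethod
    def _exact_tail(mirna: str, cutoff: float) -> float:
        """Exact P(window score <= cutoff) for a uniform random site.

        Per-position value distributions depend on the miRNA base (G can
        both pair C and wobble U, etc.); the window score's law is their
        convolution.
        """
        per_base = {
            "A": {-2.0: 0.25, 1.0: 0.75},
            "U": {-2.0: 0.25, -1.0: 0.25, 1.0: 0.5},
            "G": {-3.0: 0.25, -1.0: 0.25, 1.0: 0.5},
            "C": {-3.0: 0.25, 1.0: 0.75},
        }
        dist = {0.0: 1.0}
        for b in mirna:
            nxt: dict[float, float] = {}
            for s, p in dist.items():
                for v, q in per_base[b].items():
                    nxt[s + v] = nxt.get(s + v, 0.0) + p * q
            dist = nxt
        return sum(p for s, p in dist.items() if s <= cutoff)

    def test_chance_hit_rate_matches_null_distribution(self, rng):
        """Monte-Carlo false-hit rate on shuffled sequence vs exact law.

        At the default cutoff (-20) chance windows appear at the percent
        level (order 10 per kb); at -35 the chance rate drops below 0.05
        per kb.
        """
        from seedlnc.cerna import _window_scores

        m = "".join("ACGU"[i] for i in rng.integers(0, 4, 21))
        target = "".join("ACGU"[i] for i in rng.integers(0, 4, 200_000))
        scores = _window_scores(m, target, "lncRNA")
        n = len(scores)
        expected = self._exact_tail(m, -20.0)
        frac20 = float((scores <= -20).mean())
        sigma = (expected * (1 - expected) / n) ** 0.5
        assert abs(frac20 - expected) < 6 * sigma
        assert 0.001 < expected < 0.05  # percent-level at the default cutoff
        rate35_per_kb = float((scores <= -35).sum()) / (len(target) / 1000)
        assert self._exact_tail(m, -35.0) * 1000 < 0.05
        assert rate35_per_kb < 0.05

    def test_mrna_mode_is_highly_selective(self, rng):
        m = "".join("ACGU"[i] for i in rng.integers(0, 4, 21))
        target = "".join("ACGU"[i] for i in rng.integers(0, 4, 50_000))
        assert scan_targets("mi", m, "t", target, "mRNA") == []

    def test_planted_sites_recovered_exactly(self, default_dataset):
        """Every planted site is rediscovered at its exact coordinate."""
        ds = default_dataset
        sites = ds.truth.sites
        assert len(sites) == 2 * ds.config.n_planted_triplets
        for row in sites.itertuples():
            mode = "lncRNA" if row.target_kind == "lncRNA" else "mRNA"
            hits = scan_targets(
                row.mirna_id,
                ds.mirnas[row.mirna_id],
                row.target_id,
                ds.transcript_seqs[row.target_id],
                mode,
            )
            assert any(h.site_start == row.site_start for h in hits), row


def _hit(mid, tid, kind):
    return MiRNATargetHit(mid, tid, kind, 1, "", -30.0)


class TestBuildNetwork:
    def test_disjoint_mirnas_give_empty_network(self):
        lnc = [_hit("m1", "l1", "lncRNA")]
        mrna = [_hit("m2", "g1", "mRNA")]
        triplets, summary = build_cerna_network(lnc, mrna)
        assert triplets == [] and summary["n_triplets"] == 0

    def test_cartesian_product_on_shared_mirna(self):
        lnc = [_hit("m1", "l1", "lncRNA"), _hit("m1", "l2", "lncRNA")]
        mrna = [_hit("m1", f"g{i}", "mRNA") for i in range(3)]
        triplets, summary = build_cerna_network(lnc, mrna)
        assert len(triplets) == 6
        assert (summary["n_lncrna"], summary["n_mirna"], summary["n_mrna"]) == (2, 1, 3)

    def test_de_filter_restricts_nodes(self):
        lnc = [_hit("m1", "l1", "lncRNA"), _hit("m1", "l2", "lncRNA")]
        mrna = [_hit("m1", "g1", "mRNA")]
        triplets, _ = build_cerna_network(lnc, mrna, {"l1"}, {"g1"})
        assert [(t.lncrna_id, t.mrna_id) for t in triplets] == [("l1", "g1")]

    def test_join_matches_brute_force_on_random_instances(self, rng):
        for _ in range(10):
            n1, n2 = int(rng.integers(1, 400)), int(rng.integers(1, 400))
            lnc = [
                _hit(f"m{rng.integers(0, 20)}", f"l{rng.integers(0, 30)}", "lncRNA")
                for _ in range(n1)
            ]
            mrna = [
                _hit(f"m{rng.integers(0, 20)}", f"g{rng.integers(0, 30)}", "mRNA")
                for _ in range(n2)
            ]
            triplets, _ = build_cerna_network(lnc, mrna)
            assert {
                (t.lncrna_id, t.mirna_id, t.mrna_id) for t in triplets
            } == brute_force_join(lnc, mrna)

    def test_triplets_satisfy_two_hit_invariant(self, pipeline_run):
        lnc_pairs = {(h.mirna_id, h.target_id) for h in pipeline_run["lnc_hits"]}
        mrna_pairs = {(h.mirna_id, h.target_id) for h in pipeline_run["mrna_hits"]}
        for t in pipeline_run["triplets"]:
            assert (t.mirna_id, t.lncrna_id) in lnc_pairs
            assert (t.mirna_id, t.mrna_id) in mrna_pairs

    def test_network_edges_cover_triplets(self):
        lnc = [_hit("m1", "l1", "lncRNA")]
        mrna = [_hit("m1", "g1", "mRNA")]
        triplets, _ = build_cerna_network(lnc, mrna)
        assert network_edges(triplets) == [
            ("l1", "lncRNA-miRNA", "m1"),
            ("m1", "miRNA-mRNA", "g1"),
        ]

    def test_scan_all_is_deterministically_ordered(self, rng):
        m = {"mi_b": "ACGU" * 5 + "A", "mi_a": "UGCA" * 5 + "G"}
        t = {"t2": "ACGU" * 30, "t1": "UGCA" * 30}
        h1 = scan_all(m, t, "lncRNA", energy_cutoff=10.0)
        h2 = scan_all(m, t, "lncRNA", energy_cutoff=10.0)
        assert h1 == h2
        keys = [(h.mirna_id, h.target_id) for h in h1]
        assert keys == sorted(keys, key=lambda k: (k[0], k[1]))
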