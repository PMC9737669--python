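"""miRNA target scoring and ceRNA network assembly.

Two gapless window-scoring schemes stand in for full hybridization tools:

* lncRNA mode — a pseudo-energy over the miRNA/site duplex (G:C -3, A:U -2,
  G:U wobble -1, anything else +1; more negative is better), with hits kept
  at energy <= -20 by default.
* mRNA mode — the classic plant expectation penalty (perfect pair 0, G:U
  wobble 0.5, mismatch 1), doubled at miRNA positions 2-13 (the
  seed-critical region; position 1 never doubled), hits kept at penalty
  <= 5.0 by default.

Both scan a miRNA-length window along the target with the site read in
reverse orientation against the miRNA (5'->3' of the miRNA pairs the
3'->5' site). The ceRNA network is the join of the miRNA-lncRNA and
miRNA-mRNA hit relations on the shared miRNA. Hit lists may also be
supplied from external prediction tools, in which case only the join is
performed here.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .models import CeRNATriplet, MiRNATargetHit

RNA_ALPHABET = set("ACGU")

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}

ENERGY_CUTOFF = -20.0
EXPECTATION_CUTOFF = 5.0
SEED_REGION = (2, 13)  # miRNA positions with doubled penalties, 1-based


def _check_rna(seq: str, label: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"{label}: non-RNA characters {sorted(bad)}")
    return seq


def duplex_score(mirna: str, site: str) -> tuple[float, str]:
    """Pseudo-energy of a gapless miRNA/site duplex.

    The site is read reverse-oriented against the miRNA. Returns (energy,
    mask) where the mask marks each miRNA position '|' (Watson-Crick),
    ':' (G:U wobble) or '.' (unpaired).
    """
    mirna = _check_rna(mirna, "mirna")
    site = _check_rna(site, "site")
    if len(mirna) != len(site):
        raise ValueError("duplex_score needs equal-length miRNA and site")
    rev = site[::-1]
    energy = 0.0
    mask = []
    for a, b in zip(mirna, rev):
        pair = (a, b)
        if pair in WATSON_CRICK:
            energy += -3.0 if "G" in pair else -2.0
            mask.append("|")
        elif pair in WOBBLE:
            energy += -1.0
            mask.append(":")
        else:
            energy += 1.0
            mask.append(".")
    return energy, "".join(mask)


def expectation_score(mirna: str, target_window: str) -> float:
    """Plant-style expectation penalty for a gapless site.

    Mismatch 1, G:U 0.5, perfect pair 0; penalties are doubled where the
    miRNA position (5'->3', 1-based) falls in the seed-critical region 2-13.
    """
    mirna = _check_rna(mirna, "mirna")
    window = _check_rna(target_window, "target_window")
    if len(mirna) != len(window):
        raise ValueError("expectation_score needs window length == miRNA length")
    rev = window[::-1]
    lo, hi = SEED_REGION
    penalty = 0.0
    for i, (a, b) in enumerate(zip(mirna, rev), start=1):
        pair = (a, b)
        if pair in WATSON_CRICK:
            base = 0.0
        elif pair in WOBBLE:
            base = 0.5
        else:
            base = 1.0
        if lo <= i <= hi:
            base *= 2.0
        penalty += base
    return penalty


_CODE = {b: i for i, b in enumerate("ACGU")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq], dtype=np.int8)


def _score_tables() -> tuple[np.ndarray, np.ndarray]:
    """4x4 per-position tables mirroring the scalar scoring rules exactly."""
    energy = np.full((4, 4), 1.0)
    expect = np.full((4, 4), 1.0)
    for a, b in WATSON_CRICK:
        energy[_CODE[a], _CODE[b]] = -3.0 if "G" in (a, b) else -2.0
        expect[_CODE[a], _CODE[b]] = 0.0
    for a, b in WOBBLE:
        energy[_CODE[a], _CODE[b]] = -1.0
        expect[_CODE[a], _CODE[b]] = 0.5
    return energy, expect


_ENERGY_TABLE, _EXPECT_TABLE = _score_tables()


def _window_scores(mirna: str, target: str, mode: str) -> np.ndarray:
    """Vectorized per-window scores; equal to the scalar ops per position."""
    m = _encode(mirna)
    t = _encode(target)
    L = len(m)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)[:, ::-1]
    if mode == "lncRNA":
        return _ENERGY_TABLE[m[None, :], windows].sum(axis=1)
    per_pos = _EXPECT_TABLE[m[None, :], windows]
    lo, hi = SEED_REGION
    weights = np.where(
        (np.arange(1, L + 1) >= lo) & (np.arange(1, L + 1) <= hi), 2.0, 1.0
    )
    return (per_pos * weights[None, :]).sum(axis=1)


def scan_targets(
    mirna_id: str,
    mirna: str,
    target_id: str,
    target_sequence: str,
    mode: str,
    energy_cutoff: float = ENERGY_CUTOFF,
    expectation_cutoff: float = EXPECTATION_CUTOFF,
) -> list[MiRNATargetHit]:
    """Slide a miRNA-length window along the target and keep passing sites.

    ``mode`` is "lncRNA" (pseudo-energy <= energy_cutoff) or "mRNA"
    (expectation <= expectation_cutoff). Overlapping candidate sites are
    resolved best-score-first, leftmost on ties; reported site_start is
    1-based on the target.
    """
    if mode not in ("lncRNA", "mRNA"):
        raise ValueError("mode must be 'lncRNA' or 'mRNA'")
    mirna = _check_rna(mirna, "mirna")
    target = _check_rna(target_sequence, "target")
    L = len(mirna)
    if len(target) <= L:
        return []

    cutoff = energy_cutoff if mode == "lncRNA" else expectation_cutoff
    scores = _window_scores(mirna, target, mode)
    candidates: list[tuple[float, int, str]] = []
    for start in np.nonzero(scores <= cutoff)[0]:
        window = target[start : start + L]
        _, mask = duplex_score(mirna, window)
        candidates.append((float(scores[start]), int(start), mask))

    candidates.sort(key=lambda c: (c[0], c[1]))
    chosen: list[tuple[float, int, str]] = []
    for score, start, mask in candidates:
        if all(abs(start - s) >= L for _, s, _ in chosen):
            chosen.append((score, start, mask))
    chosen.sort(key=lambda c: c[1])
    kind = mode
    return [
        MiRNATargetHit(mirna_id, target_id, kind, start + 1, mask, score)
        for score, start, mask in chosen
    ]


def scan_all(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    mode: str,
    **cutoffs,
) -> list[MiRNATargetHit]:
    """scan_targets over every miRNA x target combination, deterministic order."""
    hits: list[MiRNATargetHit] = []
    for mid in sorted(mirnas):
        for tid in sorted(targets):
            hits.extend(
                scan_targets(mid, mirnas[mid], tid, targets[tid], mode, **cutoffs)
            )
    return hits


def build_cerna_network(
    lnc_hits: Iterable[MiRNATargetHit],
    mrna_hits: Iterable[MiRNATargetHit],
    de_lncrnas: set[str] | None = None,
    de_mrnas: set[str] | None = None,
) -> tuple[list[CeRNATriplet], dict]:
    """Join the two hit relations on the shared miRNA.

    Emits every (lncRNA, miRNA, mRNA) triplet whose miRNA hits both the
    lncRNA and the mRNA; when DE sets are given only differentially
    expressed lncRNAs/mRNAs are admitted. Returns the triplets plus a
    summary with unique node and edge counts.
    """
    lnc_pairs = {
        (h.mirna_id, h.target_id)
        for h in lnc_hits
        if de_lncrnas is None or h.target_id in de_lncrnas
    }
    mrna_pairs = {
        (h.mirna_id, h.target_id)
        for h in mrna_hits
        if de_mrnas is None or h.target_id in de_mrnas
    }
    by_mirna_lnc: dict[str, list[str]] = {}
    for m, l in sorted(lnc_pairs):
        by_mirna_lnc.setdefault(m, []).append(l)
    by_mirna_mrna: dict[str, list[str]] = {}
    for m, g in sorted(mrna_pairs):
        by_mirna_mrna.setdefault(m, []).append(g)

    triplets = [
        CeRNATriplet(l, m, g)
        for m in sorted(set(by_mirna_lnc) & set(by_mirna_mrna))
        for l in by_mirna_lnc[m]
        for g in by_mirna_mrna[m]
    ]

    graph = nx.DiGraph()
    shared = set(by_mirna_lnc) & set(by_mirna_mrna)
    for t in triplets:
        graph.add_node(t.lncrna_id, kind="lncRNA")
        graph.add_node(t.mirna_id, kind="miRNA")
        graph.add_node(t.mrna_id, kind="mRNA")
        graph.add_edge(t.lncrna_id, t.mirna_id, interaction="lncRNA-miRNA")
        graph.add_edge(t.mirna_id, t.mrna_id, interaction="miRNA-mRNA")
    summary = {
        "n_lncrna": len({t.lncrna_id for t in triplets}),
        "n_mirna": len(shared),
        "n_mrna": len({t.mrna_id for t in triplets}),
        "n_lnc_edges": len({(t.mirna_id, t.lncrna_id) for t in triplets}),
        "n_mrna_edges": len({(t.mirna_id, t.mrna_id) for t in triplets}),
        "n_triplets": len(triplets),
        "graph": graph,
    }
    return triplets, summary


def network_edges(triplets: Iterable[CeRNATriplet]) -> list[tuple[str, str, str]]:
    """Edge rows for io.write_edge_list (viewer-importable TSV)."""
    edges: set[tuple[str, str, str]] = set()
    for t in triplets:
        edges.add((t.lncrna_id, "lncRNA-miRNA", t.mirna_id))
        edges.add((t.mirna_id, "miRNA-mRNA", t.mrna_id))
    return sorted(edges)
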