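"""Independent oracle implementations used by the test suite.

Everything here is deliberately written as plain straight-line code,
separate from the package's implementations, so tests compare two
independent routes to the same answer.
"""

from __future__ import annotations

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_longest_orf(seq: str) -> int:
    """Longest ATG->stop ORF by scanning every start position."""
    seq = seq.upper()
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in STOPS:
                best = max(best, j + 3 - i)
                break
            j += 3
    return best


def naive_pearson(x, y) -> float:
    """Two-pass product-moment formula, no library calls."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (
        sum((a - mx) ** 2 for a in x) ** 0.5
        * sum((b - my) ** 2 for b in y) ** 0.5
    )
    return num / den


def straightline_cascade(
    candidates,
    fpkm_df,
    annotation,
    coding_map,
    exon_min=2,
    len_min=200,
    fpkm_min=0.5,
):
    """Plain re-application of the five identification rules, one loop each.

    Returns the surviving transcript-id set.
    """
    coding_exons = [
        (ex.chrom, ex.strand, ex.start, ex.end)
        for t in annotation
        if t.biotype == "protein_coding"
        for ex in t.exons
    ]
    survivors = set()
    for t in candidates:
        if t.interval.strand not in ("+", "-"):
            continue
        if len(t.exons) < exon_min:
            continue
        if sum(e.end - e.start + 1 for e in t.exons) < len_min:
            continue
        overlap = False
        for ex in t.exons:
            for chrom, strand, s, e in coding_exons:
                if (
                    ex.chrom == chrom
                    and ex.strand == strand
                    and ex.start <= e
                    and s <= ex.end
                ):
                    overlap = True
                    break
            if overlap:
                break
        if overlap:
            continue
        if max(fpkm_df.loc[t.transcript_id]) < fpkm_min:
            continue
        if coding_map[t.transcript_id].is_coding:
            continue
        survivors.add(t.transcript_id)
    return survivors


def brute_force_join(lnc_hits, mrna_hits):
    """Double-loop relational join on the shared miRNA id."""
    out = set()
    for h1 in lnc_hits:
        for h2 in mrna_hits:
            if h1.mirna_id == h2.mirna_id:
                out.add((h1.target_id, h1.mirna_id, h2.target_id))
    return out


def brute_force_hypergeom(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exhaustive enumeration of all n-subsets of N items."""
    from itertools import combinations

    marked = set(range(K))
    total = 0
    hit = 0
    for subset in combinations(range(N), n):
        total += 1
        if len(marked.intersection(subset)) >= k:
            hit += 1
    return hit / total


def nb_draw(rng: np.random.Generator, mu, alpha: float, size=None):
    """NB(mu, alpha) with Var = mu + alpha*mu^2 (test-local parametrization)."""
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + np.asarray(mu)), size=size)
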