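"""Hypergeometric term enrichment with rich-factor reporting.

For a study set of n genes drawn from a population of N, a term annotating
K population genes and k study genes has upper-tail probability
p = P(X >= k), X ~ Hypergeom(N, K, n), and rich factor k/K. Terms are
opaque identifiers from a gene -> term table; no ontology structure is
assumed. Significance is flagged at raw p < 0.05; BH-adjusted q-values are
reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float
    rich_factor: float
    significant: bool


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(
            f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}"
        )
    # survival function is computed in log space internally by scipy
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    study_genes: Iterable[str],
    population_genes: Iterable[str],
    term_map: pd.DataFrame | Mapping[str, list[str]],
    p_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term with >=1 study gene against the population.

    ``term_map`` is either a DataFrame with gene_id/term_id (and optional
    term_name) columns, or a mapping term_id -> list of gene ids. Results
    are sorted by (p, term_id); q is BH-adjusted across the tested terms.
    """
    study = set(study_genes)
    population = set(population_genes)
    outside = sorted(study - population)
    if outside:
        raise ValueError(f"study genes outside population: {outside[:10]}")
    if not study:
        logger.warning("empty study set; no enrichment computed")
        return []

    if isinstance(term_map, pd.DataFrame):
        names = (
            dict(zip(term_map["term_id"], term_map["term_name"]))
            if "term_name" in term_map.columns
            else {}
        )
        genes_by_term: dict[str, set[str]] = {}
        for gene, term in zip(term_map["gene_id"], term_map["term_id"]):
            genes_by_term.setdefault(term, set()).add(gene)
    else:
        names = {}
        genes_by_term = {t: set(g) for t, g in term_map.items()}

    N = len(population)
    n = len(study)
    rows = []
    for term in sorted(genes_by_term):
        term_genes = genes_by_term[term] & population
        k = len(term_genes & study)
        K = len(term_genes)
        if k == 0 or K == 0:
            continue
        rows.append(
            EnrichmentResult(
                term_id=term,
                term_name=names.get(term, term),
                k=k,
                n=n,
                K=K,
                N=N,
                p=hypergeom_p(k, K, n, N),
                q=1.0,
                rich_factor=k / K,
                significant=False,
            )
        )
    if not rows:
        logger.warning("no term annotates any study gene")
        return []
    qvals = multipletests([r.p for r in rows], method="fdr_bh")[1]
    for r, q in zip(rows, qvals):
        r.q = float(q)
        r.significant = r.p < p_threshold
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular form, including the dot-plot-ready columns (rich factor, p, count)."""
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "rich_factor": [r.rich_factor for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant for r in results],
        }
    ).set_index("term_id")
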