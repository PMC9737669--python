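"""Cis and trans target prediction for lncRNAs.

Cis targets are protein-coding genes co-localized within a +/-100 kb window
of the lncRNA span (boundary inclusive, either strand, same chromosome).
Trans targets are mRNAs whose expression profile across all samples
correlates with the lncRNA at Pearson r > 0.95 and p < 0.01 (both strict),
computed on FPKM values.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import stats

from .models import ExpressionMatrix, TargetPair, TranscriptModel

logger = logging.getLogger(__name__)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-reference p-value.

    Returns (nan, 1.0) for constant input (the pair is excluded by
    :func:`trans_targets`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("pearson: constant vector, correlation undefined")
        return float("nan"), 1.0
    r, p = stats.pearsonr(x, y)
    return float(np.clip(r, -1.0, 1.0)), float(p)


def cis_targets(
    lncrnas: Sequence[TranscriptModel],
    coding_genes: Sequence[TranscriptModel],
    window: int = 100_000,
) -> list[TargetPair]:
    """Protein-coding genes within ``window`` bases of each lncRNA span.

    A gene qualifies when its span overlaps [lnc.start - window,
    lnc.end + window] on the same chromosome, either strand; the reported
    distance is the coordinate gap between spans (0 when overlapping) and
    the window boundary is inclusive (distance == window is kept).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in coding_genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for pool in by_chrom.values():
        pool.sort(key=lambda g: g.interval.start)

    pairs: list[TargetPair] = []
    for lnc in lncrnas:
        for g in by_chrom.get(lnc.interval.chrom, []):
            if g.interval.start > lnc.interval.end + window:
                break
            d = lnc.interval.distance(g.interval)
            if d is not None and d <= window:
                pairs.append(
                    TargetPair(lnc.transcript_id, g.gene_id, "cis", distance=d)
                )
    pairs.sort(key=lambda p: (p.lncrna_id, p.gene_id))
    return pairs


def trans_targets(
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    r_min: float = 0.95,
    p_max: float = 0.01,
) -> list[TargetPair]:
    """All lncRNA x mRNA pairs passing r > r_min and p < p_max (strict).

    Both matrices must share the same samples in the same order. Pairs
    involving a constant expression vector are excluded.
    """
    if lnc_expr.sample_ids != mrna_expr.sample_ids:
        raise ValueError("lncRNA and mRNA matrices must share identical samples")
    n = len(lnc_expr.sample_ids)
    if n < 3:
        raise ValueError("need >= 3 samples for correlation")

    L = lnc_expr.values.to_numpy(dtype=float)
    M = mrna_expr.values.to_numpy(dtype=float)
    l_sd = L.std(axis=1)
    m_sd = M.std(axis=1)

    Lc = L - L.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Lc @ Mc.T) / (
            np.sqrt((Lc**2).sum(axis=1))[:, None]
            * np.sqrt((Mc**2).sum(axis=1))[None, :]
        )
    corr = np.clip(corr, -1.0, 1.0)
    corr[l_sd == 0, :] = np.nan
    corr[:, m_sd == 0] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        t = corr * np.sqrt((n - 2) / (1.0 - corr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(corr), 1.0, np.where(np.isfinite(t), p, 0.0))

    keep = (corr > r_min) & (p < p_max)
    lnc_ids = lnc_expr.transcript_ids
    mrna_ids = mrna_expr.transcript_ids
    pairs = [
        TargetPair(
            lnc_ids[i],
            mrna_ids[j],
            "trans",
            pcc=float(corr[i, j]),
            p=float(p[i, j]),
        )
        for i, j in zip(*np.nonzero(keep))
    ]
    pairs.sort(key=lambda pr: (pr.lncrna_id, pr.gene_id))
    return pairs
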