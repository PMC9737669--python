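"""Differential expression between aged and new seed libraries.

Counts are normalized with median-of-ratios size factors, per-condition
means are compared with a negative-binomial Wald test, and transcripts are
called up/down with the |log2FC| > 1, p < 0.05 criterion. FPKM computation
and the 2^-ddCt qPCR utility live here as well.

The NB Wald test models counts as NB(mu, alpha) with Var = mu + alpha*mu^2.
By default a single dispersion alpha shared across transcripts is estimated
by aggregating within-condition moments over all transcripts — with 3
replicates per condition a per-transcript moment estimate has so few
degrees of freedom that a normal-reference Wald test is badly
anti-conservative; the shared estimate keeps the test calibrated when
dispersion is approximately common, which is the regime this pipeline
targets. ``dispersion_mode="per-gene"`` switches to per-transcript moment
estimates.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import DEResult, ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_DISPERSION = 1e-8
PSEUDOCOUNT = 0.5


def compute_fpkm(
    counts: ExpressionMatrix, lengths: Mapping[str, int]
) -> ExpressionMatrix:
    """FPKM_is = counts_is * 1e9 / (length_i * total_s)."""
    if counts.kind != "counts":
        raise ValueError("compute_fpkm expects a counts matrix")
    missing = [t for t in counts.transcript_ids if t not in lengths]
    if missing:
        raise KeyError(f"lengths missing for transcripts: {missing[:5]}")
    lens = np.array([lengths[t] for t in counts.transcript_ids], dtype=float)
    if np.any(lens <= 0):
        raise ValueError("transcript lengths must be positive")
    totals = counts.values.sum(axis=0).to_numpy(dtype=float)
    zero = [s for s, tot in zip(counts.sample_ids, totals) if tot == 0]
    if zero:
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    fpkm = counts.values.to_numpy(dtype=float) * 1e9 / (lens[:, None] * totals[None, :])
    df = pd.DataFrame(fpkm, index=counts.transcript_ids, columns=counts.sample_ids)
    return ExpressionMatrix(df, counts.design, kind="fpkm")


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios per-sample scaling factors.

    factor_s = median over all-nonzero transcripts of counts_is / geomean_i.
    Falls back to total-count scaling (normalized to geometric mean 1) with
    a warning when no transcript is nonzero in every sample.
    """
    arr = counts.values.to_numpy(dtype=float)
    all_nonzero = np.all(arr > 0, axis=1)
    if not np.any(all_nonzero):
        warnings.warn(
            "no transcript with nonzero counts in all samples; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = arr.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        sub = arr[all_nonzero]
        geomeans = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / geomeans[:, None], axis=0)
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def _nb_wald(
    arr: np.ndarray,
    sf: np.ndarray,
    idx_a: list[int],
    idx_b: list[int],
    dispersion_mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log2fc, p, base_mean) for normalized counts arr / sf."""
    norm = arr / sf[None, :]
    a = norm[:, idx_a]
    b = norm[:, idx_b]
    n_a, n_b = a.shape[1], b.shape[1]

    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)

    # method-of-moments dispersion, pooled within condition
    if dispersion_mode == "shared":
        num = (var_a - mu_a).sum() + (var_b - mu_b).sum()
        den = (mu_a**2).sum() + (mu_b**2).sum()
        alpha_hat = num / den if den > 0 else MIN_DISPERSION
        if alpha_hat < MIN_DISPERSION:
            logger.info("shared dispersion estimate %.3g floored", alpha_hat)
            alpha_hat = MIN_DISPERSION
        alpha = np.full_like(mu_a, alpha_hat)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            a_a = np.where(mu_a > 0, (var_a - mu_a) / mu_a**2, 0.0)
            a_b = np.where(mu_b > 0, (var_b - mu_b) / mu_b**2, 0.0)
        alpha = (a_a + a_b) / 2
        n_floored = int((alpha < MIN_DISPERSION).sum())
        if n_floored:
            logger.info("floored %d negative dispersion estimates", n_floored)
        alpha = np.maximum(alpha, MIN_DISPERSION)

    log2fc = np.log2((mu_a + PSEUDOCOUNT) / (mu_b + PSEUDOCOUNT))
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (1.0 / np.maximum(mu_a, PSEUDOCOUNT) + alpha) / n_a + (
            1.0 / np.maximum(mu_b, PSEUDOCOUNT) + alpha
        ) / n_b
        wald = (np.log(mu_a + PSEUDOCOUNT) - np.log(mu_b + PSEUDOCOUNT)) / np.sqrt(v)
    p = np.clip(2.0 * stats.norm.sf(np.abs(wald)), 0.0, 1.0)
    return log2fc, p, norm.mean(axis=1)


def _median_of_ratios(arr: np.ndarray) -> np.ndarray | None:
    nz = np.all(arr > 0, axis=1)
    if not np.any(nz):
        return None
    sub = arr[nz]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    return np.median(sub / geo[:, None], axis=0)


def nb_test(
    counts: ExpressionMatrix,
    numerator: str = "aged",
    denominator: str = "new",
    dispersion_mode: str = "shared",
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
    refine_size_factors: bool = True,
    max_refinements: int = 8,
) -> list[DEResult]:
    """NB Wald test of numerator-vs-denominator condition means.

    log2fc = log2((mu_num + 0.5) / (mu_den + 0.5)) on the size-factor
    normalized scale; the Wald statistic compares log means with variance
    (1/mu + alpha)/n per condition; two-sided p from the normal reference;
    q is Benjamini-Hochberg. Calls use the thresholds via :func:`call_del`.

    When ``refine_size_factors`` is on (default), median-of-ratios factors
    are re-estimated on the transcripts not currently called DE and the
    test repeated until the call set stabilizes. Plain median-of-ratios
    assumes most features are unchanged; in a transcriptome where most
    lncRNAs are downregulated that assumption fails and the refinement
    restores an unbiased normalization reference.
    """
    if dispersion_mode not in ("shared", "per-gene"):
        raise ValueError("dispersion_mode must be 'shared' or 'per-gene'")
    conds = counts.conditions
    if len(conds) != 2:
        raise ValueError(f"exactly 2 conditions required, got {conds}")
    if numerator not in conds or denominator not in conds:
        raise ValueError(
            f"conditions {numerator!r}/{denominator!r} not in design ({conds})"
        )
    num_samples = counts.condition_samples(numerator)
    den_samples = counts.condition_samples(denominator)
    if len(num_samples) < 2 or len(den_samples) < 2:
        raise ValueError("need >=2 replicates per condition")
    sample_pos = {s: i for i, s in enumerate(counts.sample_ids)}
    idx_a = [sample_pos[s] for s in num_samples]
    idx_b = [sample_pos[s] for s in den_samples]

    arr = counts.values.to_numpy(dtype=float)
    sf = size_factors(counts).to_numpy()
    log2fc, p, base_mean = _nb_wald(arr, sf, idx_a, idx_b, dispersion_mode)

    if refine_size_factors:
        prev_ns: np.ndarray | None = None
        for _ in range(max_refinements):
            ns = (np.abs(log2fc) <= lfc_threshold) | (p >= p_threshold)
            if prev_ns is not None and np.array_equal(ns, prev_ns):
                break
            if ns.sum() < 10:
                logger.info("too few non-DE transcripts to refine size factors")
                break
            ref = _median_of_ratios(arr[ns])
            if ref is None:
                break
            sf = ref / np.exp(np.mean(np.log(ref)))
            log2fc, p, base_mean = _nb_wald(arr, sf, idx_a, idx_b, dispersion_mode)
            prev_ns = ns

    q = multipletests(p, method="fdr_bh")[1]

    results = [
        DEResult(tid, float(bm), float(lfc), float(pv), float(qv), "ns")
        for tid, bm, lfc, pv, qv in zip(
            counts.transcript_ids, base_mean, log2fc, p, q
        )
    ]
    up, down = call_del(results, lfc_threshold, p_threshold, use_adjusted)
    for r in results:
        r.call = "up" if r.transcript_id in up else (
            "down" if r.transcript_id in down else "ns"
        )
    return results


def call_del(
    results: Sequence[DEResult],
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> tuple[set[str], set[str]]:
    """Partition into (up, down) ids with strict |log2FC| and p thresholds."""
    up, down = set(), set()
    for r in results:
        pv = r.q if use_adjusted else r.p
        if pv < p_threshold and r.log2fc > lfc_threshold:
            up.add(r.transcript_id)
        elif pv < p_threshold and r.log2fc < -lfc_threshold:
            down.add(r.transcript_id)
    return up, down


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "baseMean": [r.base_mean for r in results],
            "log2FC": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "call": [r.call for r in results],
        }
    ).set_index("transcript_id")


def delta_delta_ct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
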