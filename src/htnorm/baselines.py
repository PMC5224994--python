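"""Comparator scaling-factor methods: library size, TMM, IMM, Bull, NHKS.

Every method returns a factor on the same ``c = S2/S1`` scale as HTN, so the
estimates are interchangeable inputs to the exact test: under the no-change
null, ``lambda_g1/N1 = c * lambda_g2/N2`` — a sample with a larger total RNA
output S dilutes each unchanged gene's depth-normalized count, so ``c`` is
the RECIPROCAL of the observed normalized fold of sample 2 over sample 1 on
non-DE genes.  In the Eq-(3)-style parameterization the depth ratio
``N1/N2`` enters the test separately, so pure library-size normalization is
the convention ``c = 1``.  The conventional TMM/IMM fold factors, defined in
the sample-2-over-sample-1 direction, are ``1/c``.
"""

from __future__ import annotations

import logging

import numpy as np

from .de import pool_replicates
from .types import CountMatrix, CountPair, HousekeepingSet, ScalingResult

__all__ = [
    "library_size_factor",
    "tmm_factor",
    "imm_factor",
    "bull_factor",
    "nhks_factor",
]

logger = logging.getLogger(__name__)


def library_size_factor() -> ScalingResult:
    """Depth-only normalization: c = 1 (N1/N2 carries the adjustment)."""
    return ScalingResult(method="library_size", c_hat=1.0)


def _positive_both(pair: CountPair):
    mask = (pair.y1 > 0) & (pair.y2 > 0)
    if not mask.any():
        raise ValueError("no gene has positive counts in both libraries")
    return mask


def tmm_factor(pair: CountPair, trim_M: float = 0.30,
               trim_A: float = 0.05) -> ScalingResult:
    """Weighted trimmed mean of M-values, sample 1 as reference.

    Genes positive in both libraries contribute a log-ratio
    ``M_g = log2((y2/N2)/(y1/N1))`` and a log-abundance
    ``A_g = 0.5*log2((y2/N2)*(y1/N1))``.  The most extreme ``trim_M``
    fraction by M (split evenly between tails) and ``trim_A`` fraction by A
    are discarded, and the surviving M are averaged with precision weights
    ``w_g = ((N1 - y1)/(N1*y1) + (N2 - y2)/(N2*y2))^-1`` (inverse delta-
    method variance of M under Poisson counts).  The trimmed weighted mean
    Mbar estimates the log fold of unchanged genes, i.e. ``-log2 c``, so the
    factor returned is ``2**(-Mbar)``.
    """
    if not (0 <= trim_M < 1 and 0 <= trim_A < 1):
        raise ValueError("trim fractions must lie in [0, 1)")
    mask = _positive_both(pair)
    y1 = pair.y1[mask].astype(float)
    y2 = pair.y2[mask].astype(float)
    N1, N2 = float(pair.N1), float(pair.N2)
    f1, f2 = y1 / N1, y2 / N2
    M = np.log2(f2 / f1)
    A = 0.5 * np.log2(f2 * f1)
    w = 1.0 / ((N1 - y1) / (N1 * y1) + (N2 - y2) / (N2 * y2))

    n = M.size
    keep = np.ones(n, dtype=bool)
    for stat, frac in ((M, trim_M), (A, trim_A)):
        k = int(np.floor(n * frac / 2.0))
        if k > 0:
            order = np.argsort(stat, kind="stable")
            keep[order[:k]] = False
            keep[order[n - k:]] = False
    if not keep.any():
        logger.warning("TMM trimming removed every gene; "
                       "falling back to the untrimmed weighted mean")
        keep[:] = True
    mbar = float(np.average(M[keep], weights=w[keep]))
    return ScalingResult(method="tmm", c_hat=float(2.0 ** (-mbar)))


def imm_factor(pair: CountPair, tol: float = 1e-6,
               max_iter: int = 100) -> ScalingResult:
    """Iterated median of fold changes.

    Starting from ``c = 1``, each round multiplies ``c`` by the median of
    the adjusted ratios ``(y1/N1) / (c * y2/N2)`` over the genes currently
    expressed in both libraries, driving the median adjusted log fold
    change to zero; convergence when ``|log2 update| < tol``.  With a fixed
    gene set the first round already lands on the median normalized ratio;
    the loop is the method's defined schedule and matters when the
    expressed-gene set is refiltered between rounds.
    """
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be positive and max_iter >= 1")
    mask = _positive_both(pair)
    ratio = (pair.y1[mask] / pair.N1) / (pair.y2[mask] / pair.N2)
    c = 1.0
    for _ in range(max_iter):
        update = float(np.median(ratio / c))
        c *= update
        if abs(np.log2(update)) < tol:
            break
    else:
        logger.warning("IMM did not converge in %d iterations; "
                       "returning the last iterate", max_iter)
    return ScalingResult(method="imm", c_hat=c)


def bull_factor(pair: CountPair, hk_gene) -> ScalingResult:
    """Single-housekeeping-gene factor: one anchor pins the scale.

    The unique c making the no-change null hold with equality for the
    chosen gene h: ``c = (y1_h/N1) / (y2_h/N2)``.
    """
    try:
        idx = pair.gene_ids.index(hk_gene)
    except ValueError:
        raise ValueError(f"housekeeping gene {hk_gene!r} not in the pair") from None
    y1, y2 = int(pair.y1[idx]), int(pair.y2[idx])
    if y1 == 0 or y2 == 0:
        raise ValueError(
            f"gene {hk_gene!r} has a zero count in one library; "
            "its normalized ratio is undefined")
    return ScalingResult(method="bull",
                         c_hat=(y1 / pair.N1) / (y2 / pair.N2))


def nhks_factor(matrix: CountMatrix, hk: HousekeepingSet,
                k: int = 15) -> ScalingResult:
    """Stability-selected housekeeping normalization.

    Ranks the candidate housekeeping genes by the coefficient of variation
    (stdev/mean) of their library-size-normalized counts across ALL samples,
    keeps the k most stable, and returns the pooled normalized ratio
    ``(sum_sel y1/N1) / (sum_sel y2/N2)`` on the condition-pooled pair.
    Requires at least two samples per condition — a single observation has
    no coefficient of variation.
    """
    levels = matrix.condition_levels()
    if len(levels) != 2:
        raise ValueError("exactly two condition labels required")
    for lab in levels:
        if matrix.samples_in(lab).size < 2:
            raise ValueError(
                f"condition {lab!r} has a single sample; the coefficient of "
                "variation cannot be computed — NHKS needs replicates")
    candidates = sorted(g for g in hk.gene_ids
                        if g in set(matrix.gene_ids))
    if not candidates:
        raise ValueError("no housekeeping genes present in the matrix")
    if k > len(candidates):
        raise ValueError(f"k = {k} exceeds the {len(candidates)} matched "
                         "housekeeping genes")

    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows = np.asarray([index[g] for g in candidates])
    norm = matrix.counts[rows] / matrix.library_sizes[np.newaxis, :]
    means = norm.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(means > 0, norm.std(axis=1, ddof=1) / means, np.inf)
    order = sorted(range(len(candidates)), key=lambda i: (cv[i], candidates[i]))
    selected = [candidates[i] for i in order[:k]]

    pooled = pool_replicates(matrix)
    sub = pooled.subset(selected)
    keep = (sub.y1 > 0) & (sub.y2 > 0)
    if not keep.all():
        dropped = [g for g, ok in zip(sub.gene_ids, keep) if not ok]
        logger.warning("NHKS dropping %d selected genes with a zero pooled "
                       "count: %s", len(dropped), dropped)
    if not keep.any():
        raise ValueError("every selected housekeeping gene has a zero pooled "
                         "count in one condition")
    num = float((sub.y1[keep] / sub.N1).sum())
    den = float((sub.y2[keep] / sub.N2).sum())
    return ScalingResult(method="nhks", c_hat=num / den)
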