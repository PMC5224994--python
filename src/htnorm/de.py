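"""Genome-wide differential-expression calling and benchmarking summaries.

Replicates within a condition are pooled by summation before testing: sums
of independent Poisson counts are Poisson, so the conditional-binomial
derivation stays exact on the pooled pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import exact_test
from .types import CountMatrix, CountPair, DESummary, HousekeepingSet, SimTruth

__all__ = [
    "pool_replicates",
    "call_de",
    "DECalls",
    "false_discovery_curve",
    "ma_values",
]

DEFAULT_CUTOFF = 1e-4


def pool_replicates(matrix: CountMatrix) -> CountPair:
    """Sum counts gene-wise within each condition; N_k sums member sizes.

    The first condition label (by order of appearance) becomes library 1.
    """
    levels = matrix.condition_levels()
    if len(levels) != 2:
        raise ValueError(
            f"exactly two condition labels required, got {levels!r}")
    idx1 = matrix.samples_in(levels[0])
    idx2 = matrix.samples_in(levels[1])
    if idx1.size == 0 or idx2.size == 0:
        raise ValueError("each condition needs at least one sample")
    return CountPair(
        matrix.gene_ids,
        matrix.counts[:, idx1].sum(axis=1),
        matrix.counts[:, idx2].sum(axis=1),
        int(matrix.library_sizes[idx1].sum()),
        int(matrix.library_sizes[idx2].sum()),
        matrix.lengths,
    )


@dataclass(frozen=True)
class DECalls:
    """Per-gene calls at a cutoff plus the direction-split summary."""

    gene_ids: tuple
    pvalues: np.ndarray
    is_de: np.ndarray
    direction: tuple  # "cond1", "cond2" or "" per gene
    summary: DESummary

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.gene_ids),
                "pvalue": self.pvalues,
                "is_de": np.asarray(self.is_de, dtype=bool),
                "direction": list(self.direction),
            }
        )


def call_de(pair: CountPair, c: float, cutoff: float = DEFAULT_CUTOFF,
            hk: HousekeepingSet | None = None,
            method: str = "htn") -> DECalls:
    """Call DE genes at ``p < cutoff`` (strict) given a scaling factor.

    A significant gene is "higher in condition 1" iff its observed count
    exceeds the conditional null mean, ``y1 > p0 * n_g`` — the comparison of
    scaled rates implied by the test statistic.  Housekeeping-subset counts
    are reported when ``hk`` is supplied.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    result = exact_test.test_pair(pair, c)
    p = result.pvalues
    with np.errstate(invalid="ignore"):
        is_de = np.isfinite(p) & (p < cutoff)
    higher1 = pair.y1 > result.p0 * pair.n
    direction = tuple(
        ("cond1" if h1 else "cond2") if de else ""
        for de, h1 in zip(is_de, higher1)
    )
    hk_mask = (np.asarray([g in hk for g in pair.gene_ids])
               if hk is not None else np.zeros(pair.n_genes, dtype=bool))
    de1 = is_de & higher1
    de2 = is_de & ~higher1
    summary = DESummary(
        method=method, cutoff=float(cutoff),
        n_higher_cond1=int(de1.sum()), n_higher_cond2=int(de2.sum()),
        hk_higher_cond1=int((de1 & hk_mask).sum()),
        hk_higher_cond2=int((de2 & hk_mask).sum()),
    )
    return DECalls(gene_ids=pair.gene_ids, pvalues=p, is_de=is_de,
                   direction=direction, summary=summary)


def false_discovery_curve(pvalues, gene_ids, truth: SimTruth,
                          max_rank: int | None = None) -> np.ndarray:
    """Running count of truly-non-DE genes among the top-r by p-value.

    Genes are ranked by ascending p-value with ties broken by gene id;
    missing (NaN) p-values rank last.  Entry ``r-1`` of the returned array
    is the number of false discoveries among the first ``r`` genes.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    gene_ids = tuple(gene_ids)
    truth_de = dict(zip(truth.gene_ids, truth.is_de))
    missing = [g for g in gene_ids if g not in truth_de]
    if missing:
        raise ValueError(f"truth does not cover genes: {missing[:5]!r}...")
    order = sorted(
        range(len(gene_ids)),
        key=lambda i: (np.isnan(pvalues[i]),
                       pvalues[i] if np.isfinite(pvalues[i]) else np.inf,
                       gene_ids[i]),
    )
    false = np.asarray([not truth_de[gene_ids[i]] for i in order], dtype=np.int64)
    curve = np.cumsum(false)
    if max_rank is not None:
        curve = curve[:max_rank]
    return curve


def ma_values(pair: CountPair) -> pd.DataFrame:
    """Per-gene (M, A) coordinates for genes positive in both libraries.

    M = log2((y2/N2)/(y1/N1)); A = 0.5*log2((y2/N2)*(y1/N1)).  Unchanged
    genes center on M = -log2(c), so the line of a normalization factor c on
    the S2/S1 scale is the horizontal M = -log2(c).
    """
    mask = (pair.y1 > 0) & (pair.y2 > 0)
    y1 = pair.y1[mask] / pair.N1
    y2 = pair.y2[mask] / pair.N2
    return pd.DataFrame(
        {
            "gene_id": [g for g, ok in zip(pair.gene_ids, mask) if ok],
            "M": np.log2(y2 / y1),
            "A": 0.5 * np.log2(y2 * y1),
        }
    )
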