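"""Conditional binomial exact test for two-library count data.

With independent Poisson counts ``Y_g1 ~ Pois(lambda_g1)`` and
``Y_g2 ~ Pois(lambda_g2)``, conditioning on the total ``n_g = Y_g1 + Y_g2``
gives ``Y_g1 | n_g ~ Binomial(n_g, p0)`` with
``p0 = lambda_g1 / (lambda_g1 + lambda_g2)``.  Under the null that gene g is
not differentially expressed at scaling factor ``c = S2/S1``,

    p0 = (c * N1/N2) / (1 + c * N1/N2),

and the two-sided p-value is the exact tail probability of falling at least
as far from the conditional mean ``p0 * n_g`` as the observation did:

    p_g(c) = P(|X - p0*n_g| >= |y_g1 - p0*n_g|),   X ~ Binomial(n_g, p0).

The criterion printed with the raw factor ``r = c*N1/N2`` — distance of
``(1+r)*Y_g1`` from ``r*n_g`` — is the same set of outcomes, since
``p0*n = r*n/(1+r)``.  Tails are evaluated with log-space binomial cdf/sf so
combined counts in the tens of millions are exact to double precision.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

from .types import CountPair, TestResult

__all__ = ["conditional_p0", "binomial_exact_pvalue", "test_pair"]

#: relative tolerance for the equality-inclusive tail comparison; boundary
#: outcomes must never be lost to rounding of p0 * n.
_TAIL_RTOL = 1e-9


def conditional_p0(c: float, N1: int, N2: int) -> float:
    """Null success probability of the conditional binomial, Eq. p0 = r/(1+r).

    Parameters
    ----------
    c
        Candidate scaling factor S2/S1 (> 0).
    N1, N2
        Library sizes (> 0).
    """
    c = float(c)
    if not np.isfinite(c) or c <= 0:
        raise ValueError("scaling factor c must be positive and finite")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    r = c * N1 / N2
    return r / (1.0 + r)


def _tail_bounds(n: np.ndarray, y1: np.ndarray, p0: float | np.ndarray):
    """Integer cut points (kl, ku) of the two-sided tail.

    The tail is ``{x : x <= kl} U {x : x >= ku}`` where kl/ku are the
    outermost integers at distance >= |y1 - p0*n| from the conditional mean,
    with a relative tolerance so exact boundary points are kept.
    """
    mean = p0 * n
    d = np.abs(y1 - mean)
    eps = _TAIL_RTOL * (1.0 + np.abs(mean) + d)
    kl = np.floor(mean - d + eps)
    ku = np.ceil(mean + d - eps)
    return kl, ku


def binomial_exact_pvalue(y1_obs: int, y2_obs: int, p0: float) -> float:
    """Two-sided exact p-value for one gene.

    Raises if ``y1_obs + y2_obs == 0`` (degenerate conditional distribution;
    callers mark such genes missing) or if ``p0`` is not in (0, 1).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    y1_obs = int(y1_obs)
    y2_obs = int(y2_obs)
    if y1_obs < 0 or y2_obs < 0:
        raise ValueError("counts must be nonnegative")
    n = y1_obs + y2_obs
    if n == 0:
        raise ValueError("n = y1 + y2 must be at least 1 (degenerate otherwise)")
    return float(_pvalues_vector(np.array([n]), np.array([y1_obs]), p0)[0])


def _pvalues_vector(n: np.ndarray, y1: np.ndarray, p0: float) -> np.ndarray:
    """Vectorized two-sided tails for genes sharing one p0; n >= 1 required."""
    kl, ku = _tail_bounds(n, y1, p0)
    # overlapping tails (observation at the conditional mean) cover everything
    overlap = kl >= ku
    lower = np.where(kl < 0, 0.0, binom.cdf(np.maximum(kl, 0), n, p0))
    upper = np.where(ku > n, 0.0, binom.sf(np.minimum(ku, n) - 1, n, p0))
    p = np.where(overlap, 1.0, lower + upper)
    return np.minimum(p, 1.0)


def pvalue_matrix(n: np.ndarray, y1: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """Two-sided tails for a grid of p0 values (rows) x genes (columns).

    Genes must satisfy ``n >= 1``.  Used by the scaling-factor grid scan,
    where the p-values of the housekeeping genes are needed at every
    candidate c simultaneously.
    """
    n = n[np.newaxis, :]
    y1 = y1[np.newaxis, :]
    p0 = np.asarray(p0, dtype=float)[:, np.newaxis]
    kl, ku = _tail_bounds(n, y1, p0)
    overlap = kl >= ku
    lower = np.where(kl < 0, 0.0, binom.cdf(np.maximum(kl, 0), n, p0))
    upper = np.where(ku > n, 0.0, binom.sf(np.minimum(ku, n) - 1, n, p0))
    p = np.where(overlap, 1.0, lower + upper)
    return np.minimum(p, 1.0)


def test_pair(pair: CountPair, c: float) -> TestResult:
    """Exact test of every gene in ``pair`` at scaling factor ``c``.

    Genes with ``n_g = 0`` receive NaN p-values and are excluded from
    ``n_tested``.
    """
    if pair.n_genes == 0:
        raise ValueError("pair contains no genes")
    p0 = conditional_p0(c, pair.N1, pair.N2)
    n = pair.n
    pvals = np.full(pair.n_genes, np.nan)
    mask = n > 0
    if mask.any():
        pvals[mask] = _pvalues_vector(n[mask], pair.y1[mask], p0)
    return TestResult(gene_ids=pair.gene_ids, pvalues=pvals, p0=p0, c=float(c))
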