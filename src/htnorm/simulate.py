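"""Synthetic two-condition RNA-seq count generator with full ground truth.

The design emulates the classic scaling-normalization benchmark: per-gene
base expression levels are resampled from an empirical pool of real-looking
counts, a stated fraction of genes receives a fold change (with an up/down
asymmetry between conditions), a stated fraction is expressed uniquely in
condition 2 (mean zero in condition 1), and a designated subset of the null
genes is flagged as housekeeping.  Per library, means are rescaled so the
expected column sum hits the target depth ``N_k`` — ``lambda_gk =
mu_gk / S_k * N_k`` with ``S_k = sum_g mu_gk`` and unit gene lengths — and
counts are drawn independently as Poisson.

Everything is deterministic given the config seed; replicate ``r`` of a
study derives its seed additively from the base seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from . import baselines, de, estimator
from .types import CountMatrix, CountPair, HousekeepingSet, SimTruth

__all__ = ["SimConfig", "default_source", "simulate_pair", "run_study"]

logger = logging.getLogger(__name__)

_POOL_CACHE: np.ndarray | None = None

COND1, COND2 = "cond1", "cond2"


def default_source() -> np.ndarray:
    """The packaged resampling pool of per-gene counts.

    A committed synthetic pool of 5000 positive integers with a heavy right
    tail (log-normal recipe documented in the data file header), standing in
    for an empirical distribution of real counts.  Users may pass their own
    pool through :class:`SimConfig`.
    """
    global _POOL_CACHE
    if _POOL_CACHE is None:
        text = (resources.files("htnorm") / "data" /
                "synthetic_count_pool.txt").read_text()
        vals = [int(line) for line in text.splitlines()
                if line.strip() and not line.startswith("#")]
        _POOL_CACHE = np.asarray(vals, dtype=np.int64)
    return _POOL_CACHE


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults are the benchmark's: 10,000 genes, 1.5-fold DE with 90% of DE
    genes higher in condition 2, 10% of genes unique to condition 2, 500
    housekeeping genes, one sample per condition at a depth of one million
    reads.  ``hk_noise_rate`` is the fraction of housekeeping labels that
    secretly point at true DE genes (the robustness sweep).
    """

    n_genes: int = 10_000
    de_rate: float = 0.1
    fold: float = 1.5
    frac_up_in_2: float = 0.9
    unique_rate: float = 0.1
    n_housekeeping: int = 500
    hk_noise_rate: float = 0.0
    library_size: int = 1_000_000
    n_reps: int = 1
    seed: int = 0
    source: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        for name in ("de_rate", "frac_up_in_2", "unique_rate", "hk_noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if self.n_genes < 1 or self.n_reps < 1 or self.library_size < 1:
            raise ValueError("n_genes, n_reps and library_size must be >= 1")

    def counts_per_class(self) -> dict:
        n_unique = int(round(self.unique_rate * self.n_genes))
        n_de = int(round(self.de_rate * self.n_genes))
        n_up = int(round(self.frac_up_in_2 * n_de))
        return {"unique_2": n_unique, "de_up_2": n_up,
                "de_down_2": n_de - n_up,
                "null": self.n_genes - n_unique - n_de}


def simulate_pair(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw one dataset (genes x samples counts) plus its ground truth."""
    classes = config.counts_per_class()
    if classes["null"] < 0:
        raise ValueError("unique_rate + de_rate exceed 1")
    n_noise = int(round(config.hk_noise_rate * config.n_housekeeping))
    n_de_total = classes["de_up_2"] + classes["de_down_2"]
    if config.n_housekeeping - n_noise > classes["null"]:
        raise ValueError("not enough null genes to host the housekeeping set")
    if n_noise > n_de_total:
        raise ValueError("not enough DE genes to host the noisy "
                         "housekeeping labels")

    rng = np.random.default_rng(config.seed)
    pool = config.source if config.source is not None else default_source()
    mu = rng.choice(pool, size=config.n_genes, replace=True).astype(float)

    perm = rng.permutation(config.n_genes)
    n_u, n_up, n_dn = (classes["unique_2"], classes["de_up_2"],
                       classes["de_down_2"])
    idx_unique = perm[:n_u]
    idx_up = perm[n_u:n_u + n_up]
    idx_down = perm[n_u + n_up:n_u + n_up + n_dn]
    idx_null = perm[n_u + n_up + n_dn:]

    label = np.full(config.n_genes, "null", dtype=object)
    label[idx_unique] = "unique_2"
    label[idx_up] = "de_up_2"
    label[idx_down] = "de_down_2"

    mu1 = mu.copy()
    mu2 = mu.copy()
    mu1[idx_unique] = 0.0
    mu2[idx_up] *= config.fold
    mu1[idx_down] *= config.fold

    is_hk = np.zeros(config.n_genes, dtype=bool)
    clean = rng.choice(idx_null, size=config.n_housekeeping - n_noise,
                       replace=False)
    is_hk[clean] = True
    if n_noise:
        idx_de = np.concatenate([idx_up, idx_down])
        noisy = rng.choice(idx_de, size=n_noise, replace=False)
        is_hk[noisy] = True

    S1, S2 = mu1.sum(), mu2.sum()
    true_c = S2 / S1
    with np.errstate(divide="ignore"):
        true_fold = np.where(mu1 > 0, mu2 / mu1, np.inf)

    columns, sample_ids, condition = [], [], []
    for cond, mu_k, S_k in ((COND1, mu1, S1), (COND2, mu2, S2)):
        lam = mu_k / S_k * config.library_size
        for rep in range(1, config.n_reps + 1):
            columns.append(rng.poisson(lam))
            sample_ids.append(f"{cond}_rep{rep}")
            condition.append(cond)
    counts = np.column_stack(columns)

    gene_ids = tuple(f"g{i+1:05d}" for i in range(config.n_genes))
    matrix = CountMatrix(gene_ids, counts, sample_ids, condition)
    truth = SimTruth(gene_ids=gene_ids, label=tuple(label),
                     is_housekeeping=is_hk, true_fold=true_fold,
                     true_c=float(true_c))
    return matrix, truth


def _select_stable_hk(matrix: CountMatrix, hk: HousekeepingSet, k: int):
    """The k candidate housekeeping genes most stable by CV across samples."""
    candidates = sorted(g for g in hk.gene_ids if g in set(matrix.gene_ids))
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows = np.asarray([index[g] for g in candidates])
    norm = matrix.counts[rows] / matrix.library_sizes[np.newaxis, :]
    means = norm.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(means > 0, norm.std(axis=1, ddof=1) / means, np.inf)
    order = sorted(range(len(candidates)), key=lambda i: (cv[i], candidates[i]))
    return [candidates[i] for i in order[:k]]


def estimate_factor(method: str, pair: CountPair, matrix: CountMatrix,
                    hk: HousekeepingSet, k: int = 15):
    """Dispatch one normalization method on a pooled pair.

    Bull and NHKS need the replicate-level matrix for their CV-based gene
    selection and therefore require at least two samples per condition.
    """
    if method == "htn":
        return estimator.estimate_c(estimator.hk_pair_from(pair, hk))
    if method in ("library", "library_size"):
        return baselines.library_size_factor()
    if method == "tmm":
        return baselines.tmm_factor(pair)
    if method == "imm":
        return baselines.imm_factor(pair)
    if method == "bull":
        gene = _select_stable_hk(matrix, hk, 1)[0]
        return baselines.bull_factor(pair, gene)
    if method == "nhks":
        return baselines.nhks_factor(matrix, hk, k=k)
    raise ValueError(f"unknown normalization method {method!r}")


def run_study(configs, methods, n_replicates: int,
              base_seed: int | None = None, max_rank: int | None = None):
    """Replicate each config, run each method, collect c_hat and FD curves.

    Returns ``(records, curves)``: a tidy DataFrame with one row per
    (config, replicate, method) holding the estimated factor and the false-
    discovery count at rank = number of truly DE genes; and a dict mapping
    ``(config_index, method)`` to the mean false-discovery curve.  A failure
    of one method on one replicate is logged and skipped, never fatal.
    """
    rows = []
    curve_sums: dict = {}
    curve_counts: dict = {}
    for ci, config in enumerate(configs):
        base = config.seed if base_seed is None else base_seed
        for r in range(n_replicates):
            cfg = replace(config, seed=base + r)
            matrix, truth = simulate_pair(cfg)
            pair = de.pool_replicates(matrix)
            hk = HousekeepingSet(
                g for g, flag in zip(truth.gene_ids, truth.is_housekeeping)
                if flag)
            n_true_de = int(truth.is_de.sum())
            for method in methods:
                try:
                    res = estimate_factor(method, pair, matrix, hk)
                    tested = de.call_de(pair, res.c_hat, method=method)
                    curve = de.false_discovery_curve(
                        tested.pvalues, pair.gene_ids, truth,
                        max_rank=max_rank)
                except Exception:
                    logger.exception(
                        "method %s failed on config %d replicate %d",
                        method, ci, r)
                    continue
                fd = int(curve[n_true_de - 1]) if n_true_de else 0
                rows.append({"config": ci, "replicate": r, "method": method,
                             "seed": cfg.seed, "true_c": truth.true_c,
                             "c_hat": res.c_hat, "n_true_de": n_true_de,
                             "fd_at_true_de": fd})
                key = (ci, method)
                if key not in curve_sums:
                    curve_sums[key] = curve.astype(float)
                    curve_counts[key] = 1
                else:
                    m = min(curve_sums[key].size, curve.size)
                    curve_sums[key] = curve_sums[key][:m] + curve[:m]
                    curve_counts[key] += 1
    curves = {key: curve_sums[key] / curve_counts[key] for key in curve_sums}
    return pd.DataFrame(rows), curves
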