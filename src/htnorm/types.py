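"""Core containers for two-library RNA-seq count data.

The unit the exact test operates on is a :class:`CountPair`: two libraries'
per-gene counts together with their library sizes ``N1`` and ``N2``.  Under
the model the expected count of gene ``g`` in library ``k`` is proportional
to ``mu_gk * L_g * N_k / S_k`` where ``S_k = sum_g mu_gk * L_g`` is the total
RNA output of the sample; gene lengths cancel in every statistic implemented
here and are carried only as optional metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountPair",
    "CountMatrix",
    "HousekeepingSet",
    "ScalingResult",
    "TestResult",
    "DESummary",
    "SimTruth",
]


def _as_count_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, rtol=0, atol=1e-9):
            raise ValueError(f"{name} must contain integers")
        arr = rounded
    arr = arr.astype(np.int64)
    if arr.size and arr.min() < 0:
        raise ValueError(f"{name} must be nonnegative")
    return arr


@dataclass(frozen=True)
class CountPair:
    """Per-gene counts of two libraries plus their library sizes.

    ``N1``/``N2`` default to the column sums but may be overridden, e.g. when
    the counts are a housekeeping subset of a larger library.
    """

    gene_ids: tuple
    y1: np.ndarray
    y2: np.ndarray
    N1: int
    N2: int
    lengths: np.ndarray | None = None

    def __init__(self, gene_ids, y1, y2, N1=None, N2=None, lengths=None):
        y1 = _as_count_array(y1, "y1")
        y2 = _as_count_array(y2, "y2")
        gene_ids = tuple(gene_ids)
        if not (len(gene_ids) == y1.size == y2.size):
            raise ValueError("gene_ids, y1 and y2 must have equal length")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene identifiers")
        N1 = int(y1.sum()) if N1 is None else int(N1)
        N2 = int(y2.sum()) if N2 is None else int(N2)
        if N1 <= 0 or N2 <= 0:
            raise ValueError("library sizes must be positive")
        if lengths is not None:
            lengths = np.asarray(lengths, dtype=float)
            if lengths.size != y1.size or (lengths.size and lengths.min() <= 0):
                raise ValueError("lengths must be positive and match the gene count")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "y1", y1)
        object.__setattr__(self, "y2", y2)
        object.__setattr__(self, "N1", N1)
        object.__setattr__(self, "N2", N2)
        object.__setattr__(self, "lengths", lengths)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n(self) -> np.ndarray:
        """Per-gene combined count ``n_g = y_g1 + y_g2``."""
        return self.y1 + self.y2

    def swap(self) -> "CountPair":
        """Exchange the two libraries (sample 2 becomes the reference)."""
        return CountPair(self.gene_ids, self.y2, self.y1, self.N2, self.N1,
                         self.lengths)

    def subset(self, gene_ids) -> "CountPair":
        """Restrict to ``gene_ids`` (order of this pair), keeping N1/N2."""
        wanted = set(gene_ids)
        idx = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        if not idx:
            raise ValueError("no requested genes present in the pair")
        idx = np.asarray(idx)
        return CountPair(
            tuple(self.gene_ids[i] for i in idx),
            self.y1[idx], self.y2[idx], self.N1, self.N2,
            None if self.lengths is None else self.lengths[idx],
        )


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples integer counts with per-sample condition labels."""

    gene_ids: tuple
    counts: np.ndarray
    sample_ids: tuple
    condition: tuple
    library_sizes: np.ndarray
    lengths: np.ndarray | None = None

    def __init__(self, gene_ids, counts, sample_ids, condition,
                 library_sizes=None, lengths=None):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples array")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, rtol=0, atol=1e-9):
                raise ValueError("counts must be integers")
            counts = rounded
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        gene_ids = tuple(gene_ids)
        sample_ids = tuple(sample_ids)
        condition = tuple(condition)
        if counts.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if len(condition) != len(sample_ids):
            raise ValueError("one condition label per sample required")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene identifiers")
        if library_sizes is None:
            library_sizes = counts.sum(axis=0)
        library_sizes = np.asarray(library_sizes, dtype=np.int64)
        if library_sizes.shape != (len(sample_ids),) or (
                library_sizes.size and library_sizes.min() <= 0):
            raise ValueError("library_sizes must be positive, one per sample")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "condition", condition)
        object.__setattr__(self, "library_sizes", library_sizes)
        object.__setattr__(self, "lengths",
                           None if lengths is None
                           else np.asarray(lengths, dtype=float))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condition_levels(self) -> tuple:
        """The distinct condition labels in order of first appearance."""
        seen: dict = {}
        for lab in self.condition:
            seen.setdefault(lab, None)
        return tuple(seen)

    def samples_in(self, label) -> np.ndarray:
        return np.asarray([i for i, lab in enumerate(self.condition)
                           if lab == label])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.gene_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class HousekeepingSet:
    """The anchor set H of genes assumed non-DE between the two conditions."""

    gene_ids: frozenset

    def __init__(self, gene_ids):
        ids = list(gene_ids)
        fs = frozenset(ids)
        if len(fs) != len(ids):
            raise ValueError("duplicate housekeeping gene identifiers")
        if not fs:
            raise ValueError("housekeeping set must be non-empty")
        object.__setattr__(self, "gene_ids", fs)

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene) -> bool:
        return gene in self.gene_ids

    def __iter__(self):
        return iter(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class TestResult:
    """Per-gene two-sided exact p-values at a fixed scaling factor ``c``.

    Genes with ``n_g = 0`` carry NaN: the conditional distribution is
    degenerate, so no p-value exists (never 0 or 1).
    """

    gene_ids: tuple
    pvalues: np.ndarray
    p0: float
    c: float

    @property
    def n_tested(self) -> int:
        return int(np.isfinite(self.pvalues).sum())

    @property
    def tested_mask(self) -> np.ndarray:
        return np.isfinite(self.pvalues)


@dataclass(frozen=True)
class ScalingResult:
    """An estimated scaling factor c = S2/S1 and how it was obtained.

    For HTN, ``per_alpha`` maps each nominal level to ``(c_hat_alpha,
    objective_at_optimum)``; comparator methods leave it empty.
    """

    method: str
    c_hat: float
    per_alpha: Mapping[float, tuple] = field(default_factory=dict)
    alpha_grid: tuple = ()
    n_housekeeping_used: int | None = None

    def __post_init__(self):
        if not np.isfinite(self.c_hat) or self.c_hat <= 0:
            raise ValueError("c_hat must be a positive finite number")
        if self.alpha_grid and set(self.per_alpha) != set(self.alpha_grid):
            raise ValueError("per_alpha keys must equal alpha_grid")

    def per_alpha_frame(self) -> pd.DataFrame:
        rows = [(a, ca, obj) for a, (ca, obj) in sorted(self.per_alpha.items())]
        return pd.DataFrame(rows, columns=["alpha", "c_hat_alpha", "objective"])


@dataclass(frozen=True)
class DESummary:
    """Direction-split DE counts at a p-value cutoff (Table-style row set)."""

    method: str
    cutoff: float
    n_higher_cond1: int
    n_higher_cond2: int
    hk_higher_cond1: int = 0
    hk_higher_cond2: int = 0

    @property
    def n_total_de(self) -> int:
        return self.n_higher_cond1 + self.n_higher_cond2

    @property
    def hk_total_de(self) -> int:
        return self.hk_higher_cond1 + self.hk_higher_cond2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": [self.method] * 6,
                "subset": ["all", "all", "all",
                           "housekeeping", "housekeeping", "housekeeping"],
                "category": ["higher_in_cond1", "higher_in_cond2", "total"] * 2,
                "count": [self.n_higher_cond1, self.n_higher_cond2,
                          self.n_total_de, self.hk_higher_cond1,
                          self.hk_higher_cond2, self.hk_total_de],
            }
        )


#: truth labels used by the simulator
TRUTH_LABELS = ("null", "de_up_2", "de_down_2", "unique_2")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated dataset: the evaluation key.

    ``label`` is one of ``null`` (no change), ``de_up_2`` / ``de_down_2``
    (1.5-fold-style change, higher in condition 2 / 1), ``unique_2`` (zero
    mean in condition 1).  ``true_c`` is the realized total-expression ratio
    S2/S1 that normalization is trying to recover.
    """

    gene_ids: tuple
    label: tuple
    is_housekeeping: np.ndarray
    true_fold: np.ndarray
    true_c: float

    def __post_init__(self):
        bad = set(self.label) - set(TRUTH_LABELS)
        if bad:
            raise ValueError(f"unknown truth labels: {sorted(bad)}")
        if len(self.label) != len(self.gene_ids):
            raise ValueError("one label per gene required")

    @property
    def is_de(self) -> np.ndarray:
        """True where the gene genuinely differs between conditions."""
        return np.asarray([lab != "null" for lab in self.label])

    def label_counts(self) -> dict:
        out = {lab: 0 for lab in TRUTH_LABELS}
        for lab in self.label:
            out[lab] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.gene_ids),
                "label": list(self.label),
                "is_housekeeping": np.asarray(self.is_housekeeping, dtype=bool),
                "true_fold": np.asarray(self.true_fold, dtype=float),
            }
        )
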