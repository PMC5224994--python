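"""Readers and writers for the plain-text tabular formats.

Native dialect is tab-delimited text: count tables are genes x samples with
gene identifiers in the first column and a header row of sample names
(``#``-prefixed comment lines allowed); housekeeping lists are one gene
identifier per line.  Gene identifiers are opaque strings — no Ensembl or
annotation-database resolution happens here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CountMatrix, HousekeepingSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_housekeeping",
    "read_conditions",
    "write_conditions",
]


def read_counts(path, sep: str = "\t", conditions=None,
                conditions_file=None) -> CountMatrix:
    """Read a gene-by-sample count table.

    ``conditions`` is an explicit label per sample (in column order);
    ``conditions_file`` a two-column sample/condition sidecar table.  With
    neither, each sample becomes its own condition — adequate for the
    two-library case.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty count file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: count table has no genes or no samples")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated gene identifier {dup[0]!r}")

    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = int(cell)
            except (TypeError, ValueError):
                # +2: one for the header row, one for 1-based numbering
                raise ValueError(
                    f"{path}, line {i + 2}, sample {col!r}: "
                    f"non-integer count {cell!r}") from None

    sample_ids = tuple(str(c) for c in df.columns)
    if conditions_file is not None:
        mapping = read_conditions(conditions_file)
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"conditions file lacks samples: {missing}")
        condition = tuple(mapping[s] for s in sample_ids)
    elif conditions is not None:
        condition = tuple(conditions)
        if len(condition) != len(sample_ids):
            raise ValueError("one condition label per sample required")
    else:
        condition = sample_ids
    return CountMatrix(tuple(str(g) for g in df.index), values,
                       sample_ids, condition)


def write_counts(matrix: CountMatrix, path, sep: str = "\t") -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep)


def read_conditions(path, sep: str = "\t") -> dict:
    """Sample-to-condition sidecar: two columns, no header."""
    df = pd.read_csv(path, sep=sep, comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample, condition)")
    return dict(zip(df[0].str.strip(), df[1].str.strip()))


def write_conditions(matrix: CountMatrix, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for s, c in zip(matrix.sample_ids, matrix.condition):
            fh.write(f"{s}{sep}{c}\n")


def read_housekeeping(path, matrix: CountMatrix) -> HousekeepingSet:
    """Read a one-ID-per-line gene list and intersect with the matrix.

    Surrounding whitespace is trimmed; the log reports how many identifiers
    were read, matched and unmatched.  Zero matches is an error.
    """
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines()
           if line.strip() and not line.lstrip().startswith("#")]
    if not ids:
        raise ValueError(f"{path}: empty housekeeping gene list")
    present = set(matrix.gene_ids)
    matched = [g for g in dict.fromkeys(ids) if g in present]
    n_unmatched = len(set(ids)) - len(matched)
    logger.info("housekeeping list %s: %d read, %d matched, %d unmatched",
                path, len(ids), len(matched), n_unmatched)
    if not matched:
        raise ValueError(
            f"{path}: none of the {len(ids)} identifiers match the count table")
    return HousekeepingSet(matched)
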