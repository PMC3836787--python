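"""Expression-matrix I/O, validation and fold-change gene selection.

The central container is :class:`ExpressionMatrix`: a genes × samples table of
intensities with an optional sample → group mapping and a scale flag saying
whether values are linear intensities or log2-transformed. Correlation-network
construction downstream consumes this container directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_groups",
    "clean",
    "fold_change_filter",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples expression table.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers as
        columns. Values are expression intensities.
    groups
        Optional mapping ``sample_id -> group label``. When present every
        sample must be covered.
    scale
        ``"linear"`` or ``"log2"``; consumed by :func:`fold_change_filter`.
    """

    data: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if len(idx) == 0:
            raise ValueError("expression matrix has no genes")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.groups:
            unknown = set(self.groups) - set(cols)
            if unknown:
                raise ValueError(
                    f"group mapping references unknown sample(s): {sorted(unknown)}"
                )
            missing = set(cols) - set(self.groups)
            if missing:
                raise ValueError(
                    f"sample(s) without group label: {sorted(missing)}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def samples_in_group(self, group: str) -> list[str]:
        if not self.groups:
            raise ValueError("no group mapping attached to this matrix")
        hit = [s for s in self.data.columns if self.groups.get(s) == group]
        if not hit:
            raise ValueError(f"unknown group label {group!r}")
        return hit

    def linear_values(self) -> pd.DataFrame:
        """Values on the linear intensity scale (2**x for log2 input)."""
        if self.scale == "log2":
            return np.power(2.0, self.data)
        return self.data


def read_expression(
    path,
    group_path=None,
    scale: str = "linear",
) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    Layout: first row sample ids, first column gene ids, numeric body. Row and
    column order are preserved as read. A non-numeric body cell is a hard
    error reported with its (1-based) row and column position in the file;
    empty cells are admitted as missing values for :func:`clean` to handle.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        keep_default_na=False, na_values=[""],
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    def _parse(cell, i: int, j: int):
        if not isinstance(cell, str):
            return cell  # already NaN from an empty field
        s = cell.strip()
        if s == "":
            return np.nan
        try:
            return float(s)
        except ValueError:
            # +2: the header row and the gene-id column occupy position 1
            raise ValueError(
                f"non-numeric cell {cell!r} at row {i + 2}, column {j + 2} of {path}"
            ) from None

    parsed = pd.DataFrame(
        {col: [_parse(v, i, j) for i, v in enumerate(df[col])]
         for j, col in enumerate(df.columns)},
        index=df.index,
    )
    groups = read_groups(group_path, parsed.columns) if group_path else {}
    return ExpressionMatrix(parsed, groups=groups, scale=scale)


def read_groups(path, sample_ids) -> dict[str, str]:
    """Read a two-column TSV ``sample_id<TAB>group``."""
    gdf = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    groups = dict(zip(gdf["sample"], gdf["group"]))
    unknown = set(groups) - set(map(str, sample_ids))
    if unknown:
        raise ValueError(f"group file references unknown sample(s): {sorted(unknown)}")
    return groups


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix in the same TSV dialect :func:`read_expression` reads."""
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def clean(matrix: ExpressionMatrix, policy: str = "drop_gene") -> ExpressionMatrix:
    """Remove missing values.

    ``drop_gene`` removes every gene containing any missing value (the count
    is logged); ``error`` raises if any missing value is present.
    """
    if policy not in ("drop_gene", "error"):
        raise ValueError(f"unknown policy {policy!r}")
    mask = matrix.data.isna().any(axis=1)
    n_bad = int(mask.sum())
    if n_bad == 0:
        return matrix
    if policy == "error":
        bad = matrix.data.index[mask][0]
        raise ValueError(f"missing value(s) present (first affected gene: {bad!r})")
    logger.info("clean: dropped %d gene(s) with missing values", n_bad)
    return replace(matrix, data=matrix.data.loc[~mask])


def fold_change_filter(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    min_fold: float = 3.0,
) -> list[str]:
    """Genes up-regulated in ``group_a`` relative to ``group_b``.

    Fold change is the ratio of group arithmetic means on the linear scale
    (log2 input is exponentiated first). Genes with
    ``mean(group_a)/mean(group_b) >= min_fold`` are returned in input order.
    Genes whose group-b mean is not positive cannot be given a fold change and
    are skipped with a warning.
    """
    if min_fold <= 0:
        raise ValueError("min_fold must be positive")
    a_cols = matrix.samples_in_group(group_a)
    b_cols = matrix.samples_in_group(group_b)
    lin = matrix.linear_values()
    mean_a = lin[a_cols].mean(axis=1)
    mean_b = lin[b_cols].mean(axis=1)

    selected: list[str] = []
    for gene in matrix.data.index:
        mb = mean_b.loc[gene]
        if mb <= 0:
            warnings.warn(
                f"gene {gene!r}: non-positive group-{group_b} mean; skipped",
                stacklevel=2,
            )
            continue
        if mean_a.loc[gene] / mb >= min_fold:
            selected.append(gene)
    return selected
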