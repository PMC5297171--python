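"""Expression-matrix data model and trimmed-mean summarization.

The central container is :class:`ExpressionMatrix`: a genes x samples table of
non-negative RPKM values (optionally paired with raw read counts) plus
per-sample metadata (sex, tissue, age).  Downstream analyses never look at
individual samples directly; they consume per-(tissue, sex) trimmed means,
computed here, which damp the influence of outlying donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SEXES = ("F", "M")

__all__ = [
    "ExpressionMatrix",
    "TissueSexSummary",
    "filter_informative_genes",
    "trimmed_mean",
    "trimmed_mean_rows",
    "summarize_by_tissue_sex",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids, entries are
        non-negative expression values (RPKM).
    metadata
        DataFrame indexed by sample id with columns ``sex`` (``"F"``/``"M"``),
        ``tissue`` and optionally ``age``.  Every column of ``values`` must
        appear in the metadata index.
    counts
        Optional raw read counts with the same shape/labels as ``values``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    counts: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        if not self.values.index.is_unique:
            raise ValueError("gene identifiers are not unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        meta = self.metadata.loc[list(self.values.columns)]
        if meta["sex"].isna().any() or (~meta["sex"].isin(VALID_SEXES)).any():
            bad = meta.index[~meta["sex"].isin(VALID_SEXES)].tolist()
            raise ValueError(f"unknown sex label for samples: {bad[:5]}")
        if meta["tissue"].isna().any():
            bad = meta.index[meta["tissue"].isna()].tolist()
            raise ValueError(f"missing tissue for samples: {bad[:5]}")
        if self.counts is not None:
            if list(self.counts.index) != list(self.values.index) or list(
                self.counts.columns
            ) != list(self.values.columns):
                raise ValueError("counts and values must share labels")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def sample_meta(self) -> pd.DataFrame:
        """Metadata aligned to the value columns."""
        return self.metadata.loc[list(self.values.columns)]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        counts = self.counts.loc[genes] if self.counts is not None else None
        return ExpressionMatrix(self.values.loc[genes], self.metadata, counts)

    def select_samples(self, sex: str | None = None, tissue: str | None = None) -> list[str]:
        meta = self.sample_meta()
        mask = pd.Series(True, index=meta.index)
        if sex is not None:
            mask &= meta["sex"] == sex
        if tissue is not None:
            mask &= meta["tissue"] == tissue
        return list(meta.index[mask])


class TissueSexSummary:
    """Per-gene trimmed-mean expression for every (tissue, sex) cell.

    ``data`` is a DataFrame indexed by gene with a (tissue, sex) MultiIndex
    on columns.  Cells with no samples are absent (no column), never zero,
    so sex-limited tissues contribute a column for one sex only.
    """

    def __init__(self, data: pd.DataFrame, counts: pd.DataFrame | None = None):
        if not isinstance(data.columns, pd.MultiIndex):
            raise ValueError("summary columns must be a (tissue, sex) MultiIndex")
        self.data = data
        self.counts = counts  # same layout, trimmed means of raw counts

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def tissues(self) -> list[str]:
        return sorted({t for t, _ in self.data.columns})

    @property
    def common_tissues(self) -> list[str]:
        """Tissues with data for both sexes."""
        by_tissue: dict[str, set[str]] = {}
        for t, s in self.data.columns:
            by_tissue.setdefault(t, set()).add(s)
        return sorted(t for t, sexes in by_tissue.items() if {"F", "M"} <= sexes)

    def cell(self, gene: str, tissue: str, sex: str) -> float:
        return float(self.data.at[gene, (tissue, sex)])

    def max_expression(self, gene: str) -> float:
        """Maximal trimmed mean over all (tissue, sex) cells, sex-limited included."""
        return float(self.data.loc[gene].max())

    def sex_slice(self, sex: str) -> pd.DataFrame:
        """Genes x tissues frame of trimmed means for one sex."""
        cols = [c for c in self.data.columns if c[1] == sex]
        out = self.data[cols]
        out.columns = [t for t, _ in cols]
        return out


def trimmed_mean(values) -> float:
    """Mean after removing the two most extreme values (one min, one max).

    For fewer than four values the plain mean is returned, since trimming
    would leave too little data.  The result always lies within the input
    range.  Ties at an extreme drop exactly one instance.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("trimmed_mean expects a 1-D collection")
    n = arr.size
    if n == 0:
        raise ValueError("trimmed_mean of empty input")
    if n <= 3:
        return float(arr.mean())
    return float((arr.sum() - arr.max() - arr.min()) / (n - 2))


def trimmed_mean_rows(arr: np.ndarray) -> np.ndarray:
    """Row-wise :func:`trimmed_mean` for a 2-D array (genes x samples)."""
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array")
    n = arr.shape[1]
    if n == 0:
        raise ValueError("no samples")
    if n <= 3:
        return arr.mean(axis=1)
    return (arr.sum(axis=1) - arr.max(axis=1) - arr.min(axis=1)) / (n - 2)


def filter_informative_genes(matrix: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Drop genes never reaching ``threshold`` RPKM in any sample.

    A gene is informative when its maximum over all samples is at least
    ``threshold`` (inclusive).  Gene order is preserved; the operation is
    idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = matrix.values.max(axis=1) >= threshold
    return matrix.subset_genes(matrix.genes[keep])


def summarize_by_tissue_sex(matrix: ExpressionMatrix) -> TissueSexSummary:
    """One trimmed mean per gene per (tissue, sex) group of samples.

    Cells for (tissue, sex) combinations with no samples are absent from the
    result rather than filled with zero, so sex-limited tissues appear under
    one sex only.
    """
    meta = matrix.sample_meta()
    cols: dict[tuple[str, str], np.ndarray] = {}
    count_cols: dict[tuple[str, str], np.ndarray] = {}
    for (tissue, sex), grp in meta.groupby(["tissue", "sex"], observed=True, sort=True):
        if len(grp) == 0:
            continue
        sub = matrix.values[list(grp.index)].to_numpy()
        cols[(tissue, sex)] = trimmed_mean_rows(sub)
        if matrix.counts is not None:
            count_cols[(tissue, sex)] = trimmed_mean_rows(
                matrix.counts[list(grp.index)].to_numpy()
            )
    data = pd.DataFrame(cols, index=matrix.genes)
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["tissue", "sex"])
    counts = None
    if matrix.counts is not None:
        counts = pd.DataFrame(count_cols, index=matrix.genes)
        counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["tissue", "sex"])
    return TissueSexSummary(data, counts)
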