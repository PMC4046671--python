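"""Expression-matrix container, TSV I/O, quantile normalization, replicate QC.

The central data structure is :class:`ExpressionMatrix`: a genes x samples
table of non-negative signal intensities (SIU) with per-gene annotation
(product description and one of sixteen functional categories) and sample
columns named by the canonical ``{condition}_{sample_type}_{replicate}``
convention, e.g. ``P_Ht_2`` for the second biological replicate of
isolated-heterocyst RNA from a phototrophic culture.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

CONDITIONS = ("P", "M", "H")
SAMPLE_TYPES = ("F", "V", "Ht")

#: The sixteen functional categories used for annotation.  "Other" collects
#: genes annotated only with a domain name; "Unknown" collects hypothetical
#: proteins.
FUNCTIONAL_CATEGORIES = (
    "N2 fixation",
    "Photosynthesis",
    "Phycobilisome",
    "CO2 uptake/fixation",
    "Central carbon metabolism",
    "Amino acid biosynthesis",
    "Electron transfer/respiration",
    "Transport",
    "Cell envelope",
    "Cofactor biosynthesis",
    "Nucleotide metabolism",
    "DNA replication/repair",
    "Transcription/translation",
    "Regulation/signaling",
    "Other",
    "Unknown",
)

_SAMPLE_RE = re.compile(r"^(P|M|H)_(F|V|Ht)_(\d+)$")

ANNOTATION_COLUMNS = ("product", "category")


class MatrixError(ValueError):
    """Structural problem in an expression table (invariant violation)."""


class ParseError(MatrixError):
    """Malformed input file; carries the offending row/column when known."""

    def __init__(self, message: str, row=None, column=None):
        detail = message
        if row is not None:
            detail += f" (row {row})"
        if column is not None:
            detail += f" (column {column!r})"
        super().__init__(detail)
        self.row = row
        self.column = column


class SampleKey(NamedTuple):
    """Identifies one microarray sample: condition x sample type x replicate.

    Conditions: P (phototrophic), M (mixotrophic), H (heterotrophic).
    Sample types: F (whole filament), V (vegetative cell), Ht (heterocyst).
    """

    condition: str
    sample_type: str
    replicate: int

    def __str__(self) -> str:
        return f"{self.condition}_{self.sample_type}_{self.replicate}"

    @classmethod
    def parse(cls, label: str) -> "SampleKey":
        m = _SAMPLE_RE.match(label)
        if m is None:
            raise ParseError(
                f"sample header {label!r} does not match "
                "'{P|M|H}_{F|V|Ht}_{replicate}'",
                column=label,
            )
        return cls(m.group(1), m.group(2), int(m.group(3)))


@dataclass
class ExpressionMatrix:
    """Genes x samples signal-intensity table with gene annotation.

    Parameters
    ----------
    values
        DataFrame indexed by gene id (locus tag) with one column per sample,
        named canonically (``P_V_1`` ...).  All entries must be finite and
        non-negative.
    annotation
        DataFrame indexed like ``values`` with columns ``product`` and
        ``category``.  Optional; a placeholder annotation is created when
        omitted.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame = None

    def __post_init__(self):
        if self.annotation is None:
            self.annotation = pd.DataFrame(
                {"product": "unannotated protein", "category": "Unknown"},
                index=self.values.index,
            )
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise MatrixError(f"duplicate gene ids: {dups}")
        cols = self.values.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise MatrixError(f"duplicate sample columns: {dups}")
        for c in cols:
            SampleKey.parse(str(c))
        vals = self.values.to_numpy()
        if vals.size:
            if not np.isfinite(vals).all():
                raise MatrixError("matrix contains NaN or infinite values; "
                                  "missing values are not permitted")
            if (vals < 0).any():
                gi, si = np.argwhere(vals < 0)[0]
                raise ParseError(
                    f"negative signal value {vals[gi, si]}",
                    row=str(idx[gi]), column=str(cols[si]),
                )
        if not self.annotation.index.equals(idx):
            raise MatrixError("annotation index does not match gene ids")
        for col in ANNOTATION_COLUMNS:
            if col not in self.annotation.columns:
                raise MatrixError(f"annotation lacks required column {col!r}")

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def sample_keys(self) -> list[SampleKey]:
        return [SampleKey.parse(str(c)) for c in self.values.columns]

    def columns_for(self, condition: str | None = None,
                    sample_type: str | None = None) -> list[str]:
        """Sample column names matching the given condition/sample type."""
        out = []
        for c in self.values.columns:
            k = SampleKey.parse(str(c))
            if condition is not None and k.condition != condition:
                continue
            if sample_type is not None and k.sample_type != sample_type:
                continue
            out.append(str(c))
        return out

    def group_values(self, condition: str, sample_type: str) -> pd.DataFrame:
        cols = self.columns_for(condition, sample_type)
        if not cols:
            raise MatrixError(
                f"no samples for condition={condition!r}, "
                f"sample_type={sample_type!r}")
        return self.values[cols]

    def group_means(self, condition: str, sample_type: str) -> pd.Series:
        """Per-gene mean over the biological replicates of one group."""
        return self.group_values(condition, sample_type).mean(axis=1)

    def subset_genes(self, gene_ids: Sequence) -> "ExpressionMatrix":
        keep = pd.Index(gene_ids)
        missing = keep.difference(self.values.index)
        if len(missing):
            raise MatrixError(f"unknown gene ids: {missing.tolist()}")
        return ExpressionMatrix(self.values.loc[keep].copy(),
                                self.annotation.loc[keep].copy())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.annotation.copy())

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (self.values.equals(other.values)
                and self.annotation.equals(other.annotation))


# -- I/O -------------------------------------------------------------------

def read_expression_table(path, sample_map: dict | None = None
                          ) -> ExpressionMatrix:
    """Read the TSV dialect: gene_id, product, category, then sample columns.

    ``sample_map`` optionally renames foreign sample headers to canonical
    ``{condition}_{sample_type}_{replicate}`` names before parsing.
    Raises :class:`ParseError` on duplicate gene ids, unparseable sample
    headers or negative values, naming the offending row/column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     float_precision="round_trip")
    if sample_map:
        df = df.rename(columns=sample_map)
    required = ["gene_id", "product", "category"]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}", column=col)
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParseError(f"duplicate gene ids: {dups}")
    df = df.set_index("gene_id")
    sample_cols = [c for c in df.columns if c not in ("product", "category")]
    for c in sample_cols:
        SampleKey.parse(str(c))
    values = df[sample_cols].astype(float)
    annotation = df[["product", "category"]]
    return ExpressionMatrix(values, annotation)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write the canonical TSV; :func:`read_expression_table` inverts it."""
    out = pd.concat([matrix.annotation[list(ANNOTATION_COLUMNS)],
                     matrix.values], axis=1)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_geo_series_matrix(path, id_map: dict | None = None) -> pd.DataFrame:
    """Minimal reader for GEO series-matrix text files.

    Extracts the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` as a DataFrame indexed by feature ID.
    ``id_map`` optionally maps platform feature IDs to locus tags; unmapped
    features are dropped.  Returns raw signals; assembling an
    :class:`ExpressionMatrix` additionally requires renaming the GSM columns
    to canonical sample keys.
    """
    lines: list[str] = []
    inside = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if inside:
                lines.append(line)
    if not lines:
        raise ParseError("no series_matrix_table block found")
    from io import StringIO
    df = pd.read_csv(StringIO("".join(lines)), sep="\t")
    df = df.set_index(df.columns[0])
    df.index = df.index.map(lambda s: str(s).strip('"'))
    if id_map is not None:
        df = df.loc[df.index.isin(id_map)]
        df.index = df.index.map(id_map)
    return df


# -- quantile normalization -----------------------------------------------

class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization across microarray samples.

    ``X`` is oriented genes x samples (each *column* is one array).  ``fit``
    computes the reference distribution — the per-rank mean of the sorted
    columns — and ``transform`` replaces each column's order statistics with
    that reference, so every transformed column carries the identical
    multiset of values while within-column rank order is preserved.  Tied
    values within a column all receive the mean of the reference values
    their ranks span.
    """

    def fit(self, X, y=None):
        X = self._check(X)
        self.reference_ = np.sort(X, axis=0).mean(axis=1)
        self.n_genes_ = X.shape[0]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = self._check(X, n_cols_min=1)
        if X.shape[0] != self.n_genes_:
            raise MatrixError(
                f"expected {self.n_genes_} genes, got {X.shape[0]}")
        out = np.empty_like(X, dtype=float)
        ref = self.reference_
        for j in range(X.shape[1]):
            out[:, j] = _map_to_reference(X[:, j], ref)
        return out

    @staticmethod
    def _check(X, n_cols_min=2):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise MatrixError("expected a 2-D genes x samples array")
        if X.shape[1] < n_cols_min:
            raise MatrixError(
                "quantile normalization needs at least two sample columns")
        return X


def _map_to_reference(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Assign reference order statistics to one column, averaging over ties."""
    order = np.argsort(col, kind="stable")
    sorted_col = col[order]
    # run starts of equal-value blocks in the sorted column
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_col) != 0])
    block_sums = np.add.reduceat(ref, starts)
    block_lens = np.diff(np.r_[starts, len(col)])
    block_means = block_sums / block_lens
    assigned = np.repeat(block_means, block_lens)
    out = np.empty_like(assigned)
    out[order] = assigned
    return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all sample columns of an expression matrix."""
    qn = QuantileNormalizer().fit(matrix.values.to_numpy())
    values = pd.DataFrame(qn.transform(matrix.values.to_numpy()),
                          index=matrix.values.index,
                          columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.annotation.copy())


# -- replicate QC ----------------------------------------------------------

def correlation_matrix(matrix: ExpressionMatrix,
                       statistic: str = "r2") -> pd.DataFrame:
    """All pairwise sample correlations: squared Pearson (``r2``) or
    Spearman rank (``spearman``).

    The returned DataFrame is symmetric with unit diagonal; R^2 between
    biological replicates of the same experiment quantifies reproducibility.
    """
    if statistic not in ("r2", "spearman"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if matrix.n_genes < 2:
        raise MatrixError("need at least 2 genes for correlations")
    sds = matrix.values.std(axis=0, ddof=0)
    dead = sds[sds == 0].index.tolist()
    if dead:
        raise MatrixError(
            f"zero-variance sample column(s), correlation undefined: {dead}")
    if statistic == "r2":
        corr = matrix.values.corr(method="pearson") ** 2
    else:
        corr = matrix.values.corr(method="spearman")
    np.fill_diagonal(corr.values, 1.0)
    return corr
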