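"""Sample-level PCA, functional-category transcript shares, expression bins.

Three descriptive views of a normalized expression matrix:

* PCA with the 27 samples as observations and genes as (centered)
  features — used to ask whether growth conditions reshape the
  transcriptome of vegetative cells, heterocysts, or both.
* Per-category percent-of-total-transcript profiles: how much of a
  sample's total signal each of the sixteen functional categories carries.
* A seven-level ordinal bin scale for absolute signal interpretation,
  from "background" (<= 150 SIU) to "very-high" (20,001–60,000 SIU), plus
  percent-of-maximum metrics for single genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix, MatrixError

#: Upper edges of the expression bins (SIU); values above the last edge are
#: clamped into the top bin.
BIN_EDGES = (150.0, 200.0, 600.0, 2000.0, 6000.0, 20000.0)
BIN_LABELS = ("background", "just-above-background", "very-low", "low",
              "moderate", "high", "very-high")
SATURATION_CEILING = 60000.0


@dataclass
class PCAResult:
    """Sample scores, gene loadings and variance-explained fractions."""

    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # genes x components
    variance_explained: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.variance_explained) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")


def pca_samples(matrix: ExpressionMatrix, k: int = 2,
                scale_genes: bool = False) -> PCAResult:
    """PCA of samples in gene space.

    Each sample (array) is one observation; each gene is one feature,
    centered across samples (and scaled to unit variance when
    ``scale_genes``).  The component sign is fixed so that each loading
    vector's largest-magnitude entry is positive, making outputs
    deterministic.
    """
    n_samples = matrix.values.shape[1]
    if n_samples < 2:
        raise MatrixError("PCA needs at least 2 samples")
    if k > min(matrix.n_genes, n_samples):
        raise ValueError(f"k={k} exceeds min(genes, samples)")
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    if np.allclose(X, X[0]):
        raise MatrixError("constant matrix has no variance to decompose")
    if scale_genes:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x k
    # deterministic sign: largest-|entry| of each loading is positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.columns,
                            columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.values.index,
                              columns=comp_names),
        variance_explained=pca.explained_variance_ratio_.copy(),
    )


def _resolve_group(matrix: ExpressionMatrix, sample_group) -> pd.Series:
    """Per-gene mean signal over a sample group.

    ``sample_group`` is either a ``"{condition}_{sample_type}"`` string
    (e.g. ``"P_Ht"``: replicate means) or an explicit list of sample
    column names.
    """
    if isinstance(sample_group, str):
        condition, sample_type = sample_group.split("_", 1)
        return matrix.group_means(condition, sample_type)
    cols = list(sample_group)
    missing = [c for c in cols if c not in matrix.values.columns]
    if missing:
        raise MatrixError(f"unknown sample columns: {missing}")
    return matrix.values[cols].mean(axis=1)


def category_profile(matrix: ExpressionMatrix, sample_group) -> pd.Series:
    """Percent of total transcript signal carried by each category.

    For the given sample group, each functional category's share is
    100 x (sum of its genes' mean signals) / (sum over all genes); the
    shares sum to 100.  Every gene must carry a category annotation.
    """
    cats = matrix.annotation["category"]
    bad = cats.index[cats.isna() | (cats.astype(str).str.len() == 0)]
    if len(bad):
        raise MatrixError(f"unannotated gene(s): {bad.tolist()}")
    signal = _resolve_group(matrix, sample_group)
    total = signal.sum()
    if total <= 0:
        raise MatrixError("sample group has zero total signal")
    shares = 100.0 * signal.groupby(cats).sum() / total
    return shares.sort_values(ascending=False)


def classify_bin(value):
    """Map a signal intensity (SIU) to its ordinal expression bin.

    Boundaries are inclusive of their stated upper endpoint: 150 ->
    background, 151 -> just-above-background, 2,000 -> low, 20,001 ->
    very-high.  Values beyond 60,000 SIU clamp into very-high.  Accepts a
    scalar or an array; negative input is rejected.
    """
    arr = np.asarray(value, dtype=float)
    if (arr < 0).any():
        raise ValueError("signal intensities must be non-negative")
    idx = np.digitize(arr, BIN_EDGES, right=True)
    labels = np.asarray(BIN_LABELS, dtype=object)[idx]
    if arr.ndim == 0:
        return str(labels)
    return labels


def percent_of_max(matrix: ExpressionMatrix, gene_id,
                   sample_group) -> float:
    """A gene's group-mean signal as percent of the group's strongest gene.

    E.g. "nifH reached 44% of the strongest heterocyst signal".
    """
    signal = _resolve_group(matrix, sample_group)
    if gene_id not in signal.index:
        raise MatrixError(f"unknown gene id {gene_id!r}")
    top = signal.max()
    if top <= 0:
        raise MatrixError("sample group has zero signal everywhere")
    return float(100.0 * signal.loc[gene_id] / top)


def bin_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Bin label for every gene x sample-group mean (one column per group)."""
    groups = sorted({(k.condition, k.sample_type)
                     for k in matrix.sample_keys})
    out = {}
    for condition, stype in groups:
        means = matrix.group_means(condition, stype)
        out[f"{condition}_{stype}"] = classify_bin(means.to_numpy())
    return pd.DataFrame(out, index=matrix.values.index)
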