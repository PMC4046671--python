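"""Two-component linear mixing model and weighted-residual outlier detector.

Whole-filament RNA is a mixture of vegetative-cell and heterocyst RNA, so
for every gene i the replicate-mean signals should satisfy

    F_i = a * V_i + b * Ht_i          (no intercept)

where a and b reflect the relative abundance of the two cell types in the
filament (roughly 0.92 and 0.08 for typical heterocyst frequencies).  Genes
that deviate from this plane carry information: a transcript whose filament
signal far exceeds a*V + b*Ht was present in intact filaments but lost from
the isolated cell fractions — the signature of cell-type-specific
degradation during cell separation (e.g. nitrogenase transcripts in
isolated heterocysts).

Deviation is scored by the weighted residual

    R_i = (F_i - a*V_i - b*Ht_i) / sqrt(V_i^2 + Ht_i^2 + F_i^2)

i.e. the residual as a proportion of the gene's overall transcript level
(the Euclidean length of the (V, Ht, F) vector), which makes residuals
comparable between weakly and strongly expressed genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import ExpressionMatrix, MatrixError, SAMPLE_TYPES

__all__ = [
    "ReductionReport", "MixtureFit", "MixtureModel",
    "reduce_dataset", "fit_mixture", "weighted_residuals", "rank_outliers",
]


class FitError(ValueError):
    pass


# -- data reduction --------------------------------------------------------

@dataclass
class ReductionReport:
    """Bookkeeping for the pre-fit gene filters of one growth condition."""

    condition: str
    genes_in: int
    genes_removed_low_signal: int
    genes_removed_variability: int
    genes_out: int
    mean_floor: float
    cv_threshold: float

    def __post_init__(self):
        expected = (self.genes_in - self.genes_removed_low_signal
                    - self.genes_removed_variability)
        if self.genes_out != expected:
            raise ValueError("reduction counts do not reconcile")


def reduce_dataset(matrix: ExpressionMatrix, condition: str,
                   mean_floor: float = 128.0,
                   cv_threshold: float = 0.5,
                   ) -> tuple[ExpressionMatrix, ReductionReport]:
    """Remove low-signal and high-variability genes for one condition.

    First drops genes whose mean over the condition's nine samples (three
    sample types x three replicates) is below ``mean_floor`` (default 128
    SIU), then drops genes whose replicate coefficient of variation exceeds
    ``cv_threshold`` within any of the three sample-type groups.  Use
    ``cv_threshold=float('inf')`` to disable the variability filter.
    """
    cols = matrix.columns_for(condition=condition)
    if not cols:
        raise MatrixError(f"condition {condition!r} absent from matrix")
    cond_values = matrix.values[cols]

    overall_mean = cond_values.mean(axis=1)
    low = overall_mean < mean_floor
    survivors = matrix.values.index[~low]

    variable = pd.Series(False, index=survivors)
    if np.isfinite(cv_threshold):
        for stype in SAMPLE_TYPES:
            grp = matrix.group_values(condition, stype).loc[survivors]
            m = grp.mean(axis=1)
            s = grp.std(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                cv = s / m
            cv = cv.fillna(0.0)
            variable |= cv > cv_threshold
    kept = survivors[~variable]

    report = ReductionReport(
        condition=condition,
        genes_in=matrix.n_genes,
        genes_removed_low_signal=int(low.sum()),
        genes_removed_variability=int(variable.sum()),
        genes_out=len(kept),
        mean_floor=mean_floor,
        cv_threshold=cv_threshold,
    )
    return matrix.subset_genes(kept), report


# -- mixing-model fit ------------------------------------------------------

@dataclass
class MixtureFit:
    """Point estimates of the mixing coefficients plus fit diagnostics."""

    a: float
    b: float
    method: str
    sse: float
    condition: str = ""
    bootstrap_ci_a: tuple[float, float] | None = None
    bootstrap_ci_b: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None

    def __post_init__(self):
        if self.sse < 0:
            raise ValueError("sse must be non-negative")
        for ci, x, name in ((self.bootstrap_ci_a, self.a, "a"),
                            (self.bootstrap_ci_b, self.b, "b")):
            if ci is not None and not (ci[0] <= x <= ci[1]):
                warnings.warn(
                    f"bootstrap CI for {name} does not contain the point "
                    f"estimate ({x:.4f} outside [{ci[0]:.4f}, {ci[1]:.4f}])")

    def predict(self, v, ht):
        return self.a * np.asarray(v, float) + self.b * np.asarray(ht, float)


class MixtureModel(RegressorMixin, BaseEstimator):
    """No-intercept regression of filament on cell-type signals.

    scikit-learn estimator: ``X`` has two columns, the per-gene
    vegetative-cell and heterocyst replicate means (V, Ht); ``y`` is the
    filament mean F.  ``fit`` estimates the mixing coefficients
    (``a_`` for V, ``b_`` for Ht) through the origin; coefficients are not
    constrained in sign or to sum to one (real data can yield a > 1 or
    b < 0, which is itself diagnostic).

    Parameters
    ----------
    method : {"ols", "grid"}
        "ols" minimizes the plain sum of squared residuals in closed form.
        "grid" exhaustively searches the (a, b) lattice minimizing the sum
        of squared *weighted* residuals (each residual divided by the
        gene's vector norm), keeping the search coherent with the outlier
        statistic.
    a_grid, b_grid : (lo, hi, step)
        Lattice specification for the grid search.
    n_boot : int
        Number of gene-level bootstrap resamples for 95% percentile
        confidence intervals (0 disables).
    seed : int or None
        Seed for the bootstrap resampling.
    """

    def __init__(self, method: str = "ols",
                 a_grid: tuple = (0.0, 1.5, 0.001),
                 b_grid: tuple = (-0.3, 0.5, 0.001),
                 n_boot: int = 0, seed: int | None = None):
        self.method = method
        self.a_grid = a_grid
        self.b_grid = b_grid
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise FitError("X must have exactly two columns (V, Ht)")
        if X.shape[0] != y.shape[0]:
            raise FitError("X and y have different gene counts")
        if X.shape[0] < 3:
            raise FitError("need at least 3 genes to fit the mixture")
        if self.method not in ("ols", "grid"):
            raise FitError(f"unknown method {self.method!r}")
        v, ht = X[:, 0], X[:, 1]

        self.a_, self.b_, self.sse_ = self._fit_once(v, ht, y)
        self.coef_ = np.array([self.a_, self.b_])

        if self.n_boot:
            rng = np.random.default_rng(self.seed)
            n = len(y)
            boots = np.empty((self.n_boot, 2))
            for i in range(self.n_boot):
                idx = rng.integers(0, n, size=n)
                boots[i, 0], boots[i, 1], _ = self._fit_once(
                    v[idx], ht[idx], y[idx])
            lo_a, hi_a = np.percentile(boots[:, 0], [2.5, 97.5])
            lo_b, hi_b = np.percentile(boots[:, 1], [2.5, 97.5])
            self.bootstrap_ci_a_ = (float(lo_a), float(hi_a))
            self.bootstrap_ci_b_ = (float(lo_b), float(hi_b))
        else:
            self.bootstrap_ci_a_ = None
            self.bootstrap_ci_b_ = None
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_

    # -- internals --------------------------------------------------------

    def _fit_once(self, v, ht, f):
        if self.method == "ols":
            return self._fit_ols(v, ht, f)
        return self._fit_grid(v, ht, f)

    @staticmethod
    def _fit_ols(v, ht, f):
        """Closed-form least squares through the origin on (V, Ht) -> F."""
        G = np.array([[v @ v, v @ ht], [v @ ht, ht @ ht]])
        if np.linalg.matrix_rank(G) < 2:
            raise FitError("V and Ht columns are collinear; fit is singular")
        rhs = np.array([v @ f, ht @ f])
        a, b = np.linalg.solve(G, rhs)
        resid = f - a * v - b * ht
        return float(a), float(b), float(resid @ resid)

    def _fit_grid(self, v, ht, f):
        """Exhaustive lattice search minimizing the weighted-residual SSE.

        The objective sum_i ((F - aV - bHt)/norm_i)^2 is quadratic in
        (a, b), so it collapses to six precomputed scalars and the lattice
        is evaluated by broadcasting.
        """
        norm2 = v * v + ht * ht + f * f
        if (norm2 == 0).any():
            keep = norm2 > 0
            v, ht, f, norm2 = v[keep], ht[keep], f[keep], norm2[keep]
        w = 1.0 / norm2
        svv = w @ (v * v)
        shh = w @ (ht * ht)
        svh = w @ (v * ht)
        svf = w @ (v * f)
        shf = w @ (ht * f)
        sff = w @ (f * f)
        if svv * shh - svh * svh <= 0:
            raise FitError("V and Ht columns are collinear; fit is singular")
        a_lo, a_hi, a_step = self.a_grid
        b_lo, b_hi, b_step = self.b_grid
        a_vals = np.arange(a_lo, a_hi + 0.5 * a_step, a_step)
        b_vals = np.arange(b_lo, b_hi + 0.5 * b_step, b_step)
        A = a_vals[:, None]
        B = b_vals[None, :]
        obj = (A * A * svv + B * B * shh + 2 * A * B * svh
               - 2 * A * svf - 2 * B * shf + sff)
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        return float(a_vals[i]), float(b_vals[j]), float(max(obj[i, j], 0.0))


def fit_mixture(v_means, ht_means, f_means, method: str = "ols",
                a_grid: tuple = (0.0, 1.5, 0.001),
                b_grid: tuple = (-0.3, 0.5, 0.001),
                n_boot: int = 0, seed: int | None = None,
                condition: str = "") -> MixtureFit:
    """Fit F = a*V + b*Ht through the origin; see :class:`MixtureModel`.

    Inputs are the per-gene replicate means aligned by gene.  Empty or
    collinear inputs raise :class:`FitError`.
    """
    v = np.asarray(v_means, dtype=float)
    ht = np.asarray(ht_means, dtype=float)
    f = np.asarray(f_means, dtype=float)
    if v.size == 0:
        raise FitError("empty input")
    est = MixtureModel(method=method, a_grid=a_grid, b_grid=b_grid,
                       n_boot=n_boot, seed=seed)
    est.fit(np.column_stack([v, ht]), f)
    return MixtureFit(a=est.a_, b=est.b_, method=method, sse=est.sse_,
                      condition=condition,
                      bootstrap_ci_a=est.bootstrap_ci_a_,
                      bootstrap_ci_b=est.bootstrap_ci_b_,
                      n_boot=n_boot, seed=seed)


# -- weighted residuals and outlier ranking --------------------------------

def weighted_residuals(fit: MixtureFit, v_means, ht_means, f_means,
                       gene_ids=None) -> pd.DataFrame:
    """Per-gene weighted residuals R = (F - aV - bHt) / ||(V, Ht, F)||.

    Returns a DataFrame indexed by gene id with columns ``f_mean``,
    ``v_mean``, ``ht_mean``, ``f_calc``, ``vector_norm``, ``r`` and a
    1-based ``rank`` by |R| descending.  Genes with V = Ht = F = 0 have an
    undefined norm and are excluded with a warning.
    """
    v = np.asarray(v_means, dtype=float)
    ht = np.asarray(ht_means, dtype=float)
    f = np.asarray(f_means, dtype=float)
    if not (len(v) == len(ht) == len(f)):
        raise ValueError("mean vectors are not aligned")
    if gene_ids is None:
        gene_ids = pd.RangeIndex(len(v)).map(lambda i: f"gene{i}")
    gene_ids = pd.Index(gene_ids)

    norm = np.sqrt(v * v + ht * ht + f * f)
    ok = norm > 0
    if (~ok).any():
        warnings.warn(
            f"excluding {int((~ok).sum())} gene(s) with V=Ht=F=0 "
            "(vector norm undefined)")
    f_calc = fit.a * v + fit.b * ht
    r = np.where(ok, (f - f_calc) / np.where(ok, norm, 1.0), np.nan)

    df = pd.DataFrame({
        "f_mean": f, "v_mean": v, "ht_mean": ht,
        "f_calc": f_calc, "vector_norm": norm, "r": r,
    }, index=gene_ids)
    df = df[ok]
    order = df["r"].abs().sort_values(ascending=False, kind="stable").index
    df["rank"] = pd.Series(np.arange(1, len(df) + 1), index=order)
    return df


def rank_outliers(records: pd.DataFrame, k: int,
                  direction: str = "both") -> pd.DataFrame:
    """Top-k outlier genes from a weighted-residual table.

    direction "both" ranks by |R| descending (degradation in either
    fraction); "f_high" by signed R descending (filament signal exceeds
    the mixture prediction — transcripts lost from isolated cells);
    "f_low" by signed R ascending.  Ties break lexicographically by gene
    id.  Returns the top-k rows with a fresh 1-based ``rank`` column.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(records):
        raise ValueError(f"k={k} exceeds record count {len(records)}")
    if direction not in ("both", "f_high", "f_low"):
        raise ValueError(f"unknown direction {direction!r}")
    df = records.copy()
    if direction == "both":
        key = -df["r"].abs()
    elif direction == "f_high":
        key = -df["r"]
    else:
        key = df["r"]
    helper = pd.DataFrame({"key": np.asarray(key),
                           "gene": np.asarray(df.index, dtype=object)})
    order = helper.sort_values(["key", "gene"], kind="stable").index
    out = df.iloc[order].head(k).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def condition_means(matrix: ExpressionMatrix, condition: str):
    """Convenience: (V, Ht, F) replicate-mean vectors for one condition."""
    v = matrix.group_means(condition, "V")
    ht = matrix.group_means(condition, "Ht")
    f = matrix.group_means(condition, "F")
    return v, ht, f
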