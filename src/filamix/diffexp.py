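"""Vegetative-cell vs heterocyst differential expression.

Per gene and growth condition: replicate-group means, fold change (ratio of
means, heterocyst over vegetative by default), a two-tailed Welch t-test
(unequal variances, Welch–Satterthwaite degrees of freedom), and the
volcano classification — "upregulated" means a more than ``fold_threshold``
difference with p below ``alpha`` (defaults 2-fold, 0.01), in either
direction.

Tests run on log2-transformed signals by default (variance stabilization of
multiplicative noise); the raw-scale path is available via
``log_transform=False``.  No multiple-testing correction drives the
classification (the classification is on raw p-values); a
Benjamini–Hochberg FDR column can be added for modern workflows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

#: Positivity floor (SIU) applied before ratios and log transforms; below
#: background resolution.
EPSILON_FLOOR = 1.0

VOLCANO_CLASSES = ("up_in_Ht", "up_in_V", "ns")


@dataclass
class VolcanoCounts:
    up_in_V: int
    up_in_Ht: int

    @property
    def total(self) -> int:
        return self.up_in_V + self.up_in_Ht


def group_means_and_fold(matrix: ExpressionMatrix, condition: str,
                         eps: float = EPSILON_FLOOR) -> pd.DataFrame:
    """Per-gene V and Ht replicate means, fold change and log2 fold change.

    Fold is the ratio of means (not the mean of ratios), oriented
    heterocyst over vegetative.  Means below ``eps`` are clamped to ``eps``
    before the ratio; affected genes are flagged in the ``clamped`` column.
    """
    v = matrix.group_means(condition, "V")
    ht = matrix.group_means(condition, "Ht")
    clamped = (v < eps) | (ht < eps)
    v_c = v.clip(lower=eps)
    ht_c = ht.clip(lower=eps)
    fold = ht_c / v_c
    return pd.DataFrame({
        "v_mean": v, "ht_mean": ht,
        "fold": fold, "log2fc": np.log2(fold),
        "clamped": clamped,
    })


def welch_test(group1, group2, log_transform: bool = True,
               eps: float = EPSILON_FLOOR):
    """Two-tailed Welch t-test between two replicate groups.

    Returns ``(t_stat, df, p)``.  With ``log_transform`` (the default)
    signals are clamped at ``eps`` and log2-transformed first.  Degenerate
    inputs follow explicit conventions: both groups constant and equal
    gives p = 1; zero variance with unequal means gives the p -> 0 limit.
    Both emit a warning.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if log_transform:
        x = np.log2(np.clip(x, eps, None))
        y = np.log2(np.clip(y, eps, None))
    t, df, p = _welch_arrays(x[None, :], y[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def _welch_arrays(X: np.ndarray, Y: np.ndarray):
    """Row-wise Welch statistic, Welch–Satterthwaite df and two-tailed p.

    X, Y: (n_genes, n_replicates) arrays.  Rows where both groups have zero
    variance are handled by convention (equal means -> t=0, p=1; unequal
    means -> |t|=inf, p=0) with a warning.
    """
    n1, n2 = X.shape[1], Y.shape[1]
    m1, m2 = X.mean(axis=1), Y.mean(axis=1)
    v1 = X.var(axis=1, ddof=1)
    v2 = Y.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2

    degenerate = se2 == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero variance in both "
            "groups; p set by convention (1 if means equal, 0 otherwise)")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1))
                         + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
    # conventions for degenerate rows
    eq = degenerate & (m1 == m2)
    ne = degenerate & (m1 != m2)
    t = np.where(eq, 0.0, t)
    with np.errstate(invalid="ignore"):
        t = np.where(ne, np.sign(m1 - m2) * np.inf, t)
    df = np.where(degenerate, max(n1, n2) - 1.0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(eq, 1.0, p)
    p = np.where(ne, 0.0, p)
    return t, df, p


def differential_expression(matrix: ExpressionMatrix, condition: str,
                            log_transform: bool = True,
                            eps: float = EPSILON_FLOOR,
                            fdr: bool = False) -> pd.DataFrame:
    """Full per-gene differential-expression table for one condition.

    Columns: v_mean, ht_mean, fold, log2fc, t_stat, df, p (and ``fdr`` if
    requested).  The t statistic is oriented Ht minus V, so positive t
    accompanies fold > 1.  Feed the result to :func:`volcano_classify`.
    """
    base = group_means_and_fold(matrix, condition, eps=eps)
    V = matrix.group_values(condition, "V").to_numpy(dtype=float)
    Ht = matrix.group_values(condition, "Ht").to_numpy(dtype=float)
    if V.shape[1] < 2 or Ht.shape[1] < 2:
        raise ValueError("need at least 2 replicates per group")
    if log_transform:
        V = np.log2(np.clip(V, eps, None))
        Ht = np.log2(np.clip(Ht, eps, None))
    t, df, p = _welch_arrays(Ht, V)
    out = base.copy()
    out["t_stat"] = t
    out["df"] = df
    out["p"] = p
    out["condition"] = condition
    if fdr:
        out["fdr"] = _benjamini_hochberg(p)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def volcano_classify(de_records: pd.DataFrame, fold_threshold: float = 2.0,
                     alpha: float = 0.01
                     ) -> tuple[pd.DataFrame, VolcanoCounts]:
    """Classify genes as up_in_Ht / up_in_V / ns and count each direction.

    Strict inequalities: up_in_Ht requires fold (Ht/V) > ``fold_threshold``
    and p < ``alpha``; up_in_V requires the reciprocal fold to exceed the
    threshold at the same significance.  The classes are mutually
    exclusive.  Empty input yields zero counts.
    """
    df = de_records.copy()
    sig = df["p"] < alpha
    up_ht = sig & (df["fold"] > fold_threshold)
    up_v = sig & (df["fold"] < 1.0 / fold_threshold)
    df["volcano_class"] = np.select([up_ht, up_v], ["up_in_Ht", "up_in_V"],
                                    default="ns")
    return df, VolcanoCounts(up_in_V=int(up_v.sum()),
                             up_in_Ht=int(up_ht.sum()))
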