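"""Synthetic filament-transcriptome experiments with known ground truth.

The generator emulates the statistical structure the mixing-model analysis
assumes: two latent cell-type expression profiles (right-skewed,
lognormal, roughly 50–60,000 SIU), filament samples formed as the linear
mixture F = a*V + b*Ht with a ≈ 0.92 and b ≈ 0.08 (the vegetative-cell and
heterocyst shares of a filament), multiplicative lognormal replicate
noise, a background floor and saturation ceiling, a configurable set of
genes differentially expressed between the cell types, and a configurable
set of transcripts degraded specifically in isolated-heterocyst samples —
the artifact that rapid post-separation degradation of nitrogenase (nif1)
transcripts imprints on real data.

Crucially, degradation is applied to the heterocyst *samples* only, after
mixing: filaments keep the undegraded heterocyst contribution, which is
exactly the discrepancy the weighted-residual outlier statistic detects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .matrix import (ExpressionMatrix, FUNCTIONAL_CATEGORIES, SAMPLE_TYPES,
                     write_expression_table)

__all__ = ["SimulationParams", "SyntheticTruth", "simulate_dataset",
           "degrade_transcripts", "sample_replicates"]


class SimulationError(ValueError):
    """Invalid simulation parameters; the message names the field."""


@dataclass
class SimulationParams:
    """Study-design and noise parameters of one synthetic experiment.

    Defaults mirror the real study's design: 5,657 genes, three biological
    replicates per sample type, mixing weights a=0.92 / b=0.08, signals
    floored at 50 SIU and saturating at 60,000 SIU (the top of the
    "very-high" bin).  ``degradation_factor`` is the multiplier delta in
    (0, 1] applied to ``degraded_gene_count`` transcripts in
    isolated-heterocyst samples only; those transcripts are generated as
    heterocyst-specific (upregulated in Ht by ``degraded_log2fc_range``
    log2 units, matching heterocyst signals ~10x the filament signal for
    nitrogenase transcripts).
    """

    n_genes: int = 5657
    conditions: tuple = ("P",)
    n_replicates: int = 3
    mix_a: float = 0.92
    mix_b: float = 0.08
    lognormal_meanlog: float = 6.0
    lognormal_sdlog: float = 1.3
    noise_cv: float = 0.1
    background_floor: float = 50.0
    de_fraction: float = 0.3
    de_log2fc_range: tuple = (2.0, 5.0)
    degraded_gene_count: int = 10
    degradation_factor: float = 0.1
    degraded_log2fc_range: tuple = (4.5, 6.5)
    saturation_ceiling: float | None = 60000.0
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.n_genes > 0, "n_genes must be positive"),
            (len(self.conditions) > 0, "conditions must be non-empty"),
            (self.n_replicates >= 1, "n_replicates must be >= 1"),
            (self.mix_a > 0, "mix_a must be > 0"),
            (self.mix_b >= 0, "mix_b must be >= 0"),
            (self.noise_cv >= 0, "noise_cv must be >= 0"),
            (self.background_floor >= 0,
             "background_floor must be >= 0"),
            (0 <= self.de_fraction <= 1,
             "de_fraction must be a fraction in [0, 1]"),
            (0 < self.degradation_factor <= 1,
             "degradation_factor must be in (0, 1]"),
            (0 <= self.degraded_gene_count <= self.n_genes,
             "degraded_gene_count must be between 0 and n_genes"),
            (self.saturation_ceiling is None
             or self.saturation_ceiling > self.background_floor,
             "saturation_ceiling must exceed background_floor"),
        ]
        for ok, msg in checks:
            if not ok:
                raise SimulationError(msg)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["de_log2fc_range"] = list(self.de_log2fc_range)
        d["degraded_log2fc_range"] = list(self.degraded_log2fc_range)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment, for parameter-recovery tests."""

    true_v: pd.Series
    true_ht: pd.Series
    de_genes: dict            # gene_id -> true log2 fold change (Ht over V)
    degraded_genes: set
    mix_a: float
    mix_b: float

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"true_v": self.true_v, "true_ht": self.true_ht})
        df["is_de"] = df.index.isin(self.de_genes)
        df["true_log2fc"] = [self.de_genes.get(g, 0.0) for g in df.index]
        df["is_degraded"] = df.index.isin(self.degraded_genes)
        df.index.name = "gene_id"
        return df


def degrade_transcripts(ht_values: pd.Series, gene_ids, factor: float
                        ) -> pd.Series:
    """Scale the listed genes by ``factor`` (0 < factor <= 1); others unchanged.

    Models transcripts targeted for rapid degradation in heterocysts upon
    separation from the filament.  Unknown gene ids raise with the full
    offender list.
    """
    if not (0 < factor <= 1):
        raise SimulationError("degradation factor must be in (0, 1]")
    ids = pd.Index(list(gene_ids))
    unknown = ids.difference(ht_values.index)
    if len(unknown):
        raise SimulationError(f"unknown gene id(s): {unknown.tolist()}")
    out = ht_values.copy()
    out.loc[ids] = out.loc[ids] * factor
    return out


def sample_replicates(expected, n: int, cv: float, floor: float,
                      seed, ceiling: float | None = None) -> np.ndarray:
    """Draw ``n`` replicate signal vectors around an expected profile.

    Noise is multiplicative lognormal with unit mean and coefficient of
    variation ``cv`` (sigma^2 = ln(1 + cv^2), mu = -sigma^2/2), so
    replicates stay positive and right-skewed like microarray intensities.
    Values are clamped below at ``floor`` and above at ``ceiling`` when
    set.  ``seed`` may be an int or an existing Generator.
    """
    expected = np.asarray(expected, dtype=float)
    if (expected < 0).any():
        raise SimulationError("expected signals must be non-negative")
    if cv < 0:
        raise SimulationError("noise_cv must be >= 0")
    if n < 1:
        raise SimulationError("n_replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if cv == 0:
        draws = np.tile(expected, (n, 1))
    else:
        sigma = math.sqrt(math.log1p(cv * cv))
        mu = -0.5 * sigma * sigma
        noise = rng.lognormal(mean=mu, sigma=sigma,
                              size=(n, expected.size))
        draws = expected[None, :] * noise
    draws = np.clip(draws, floor, ceiling)
    return draws


def simulate_dataset(params: SimulationParams
                     ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate one synthetic experiment and its ground truth.

    Per gene, a lognormal baseline gives both cell types' noiseless
    expression; DE genes get their effect applied symmetrically (half up
    in heterocysts, half up in vegetative cells).  Sample expectations are
    V, Ht and F = mix_a*V + mix_b*Ht; degraded genes are scaled by
    ``degradation_factor`` in the heterocyst samples only (the filament
    keeps the undegraded contribution).  Replicates add multiplicative
    noise and are clamped to [floor, ceiling].  Identical parameters and
    seed give identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    width = len(str(n))
    gene_ids = pd.Index([f"gene_{i:0{width}d}" for i in range(n)],
                        name="gene_id")

    lo, hi = params.background_floor, params.saturation_ceiling
    base = rng.lognormal(params.lognormal_meanlog, params.lognormal_sdlog,
                         size=n)
    base = np.clip(base, max(lo, 1.0), hi)

    true_v = pd.Series(base.copy(), index=gene_ids)
    true_ht = pd.Series(base.copy(), index=gene_ids)
    de_genes = {}

    # transcripts degraded in isolated heterocysts (nif1-like): these are
    # heterocyst-specific transcripts, strongly upregulated in Ht — that
    # upregulation is what makes their later degradation detectable
    deg_idx = rng.choice(n, size=params.degraded_gene_count, replace=False)
    deg_fc = rng.uniform(*params.degraded_log2fc_range,
                         size=params.degraded_gene_count)
    for j, gi in enumerate(deg_idx):
        true_ht.iloc[gi] *= 2.0 ** deg_fc[j]
        de_genes[gene_ids[gi]] = float(deg_fc[j])
    degraded = set(gene_ids[deg_idx])

    # planted differential expression: half up in Ht, half up in V
    eligible = np.setdiff1d(np.arange(n), deg_idx)
    n_de = min(int(round(params.de_fraction * n)), len(eligible))
    de_idx = rng.choice(eligible, size=n_de, replace=False)
    fc_lo, fc_hi = params.de_log2fc_range
    log2fc = rng.uniform(fc_lo, fc_hi, size=n_de)
    up_in_ht = np.zeros(n_de, dtype=bool)
    up_in_ht[: n_de // 2] = True
    up_in_ht = rng.permutation(up_in_ht)
    for j, gi in enumerate(de_idx):
        g = gene_ids[gi]
        if up_in_ht[j]:
            true_ht.iloc[gi] *= 2.0 ** log2fc[j]
            de_genes[g] = float(log2fc[j])
        else:
            true_v.iloc[gi] *= 2.0 ** log2fc[j]
            de_genes[g] = float(-log2fc[j])
    true_v = true_v.clip(lower=lo, upper=hi)
    true_ht = true_ht.clip(lower=lo, upper=hi)

    ht_degraded = degrade_transcripts(true_ht, degraded,
                                      params.degradation_factor)

    expectations = {
        "V": true_v.to_numpy(),
        "Ht": ht_degraded.to_numpy(),
        "F": params.mix_a * true_v.to_numpy()
             + params.mix_b * true_ht.to_numpy(),
    }

    columns = {}
    for condition in params.conditions:
        for stype in SAMPLE_TYPES:  # F, V, Ht
            draws = sample_replicates(expectations[stype],
                                      params.n_replicates,
                                      params.noise_cv, lo, rng, hi)
            for rep in range(params.n_replicates):
                columns[f"{condition}_{stype}_{rep + 1}"] = draws[rep]
    values = pd.DataFrame(columns, index=gene_ids)

    annotation = pd.DataFrame({
        "product": "simulated protein",
        "category": _draw_categories(rng, n),
    }, index=gene_ids)

    matrix = ExpressionMatrix(values, annotation)
    truth = SyntheticTruth(true_v=true_v, true_ht=true_ht,
                           de_genes=de_genes, degraded_genes=degraded,
                           mix_a=params.mix_a, mix_b=params.mix_b)
    return matrix, truth


def _draw_categories(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random functional categories, weighted so that the catch-all
    "Other" and "Unknown" classes dominate as in real genome annotation
    (~32% and ~39% of genes respectively)."""
    cats = np.asarray(FUNCTIONAL_CATEGORIES, dtype=object)
    w = np.full(len(cats), (1.0 - 0.32 - 0.39) / (len(cats) - 2))
    w[list(cats).index("Other")] = 0.32
    w[list(cats).index("Unknown")] = 0.39
    return rng.choice(cats, size=n, p=w / w.sum())


def write_simulation(out_dir, matrix: ExpressionMatrix,
                     truth: SyntheticTruth,
                     params: SimulationParams) -> None:
    """Write matrix.tsv, truth.tsv and params.yaml into ``out_dir``."""
    import os
    import yaml
    os.makedirs(out_dir, exist_ok=True)
    write_expression_table(matrix, os.path.join(out_dir, "matrix.tsv"))
    truth.frame().to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t")
    with open(os.path.join(out_dir, "params.yaml"), "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
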