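# filamix

Deconvolution and QC of two-cell-type transcriptomes in heterocyst-forming
cyanobacterial filaments.

## The problem

In filamentous cyanobacteria such as *Anabaena*, a filament grown without
combined nitrogen contains two cell types: photosynthetic vegetative cells
(~90–95% of cells) and N₂-fixing heterocysts (~5–10%). Transcriptome
experiments on such cultures measure three kinds of RNA preparation:
whole filaments (F), vegetative-cell fractions (V) and isolated
heterocysts (Ht). Because a filament is physically a mixture of the two
cell types, every gene *i* should obey the linear mixing model

    F_i = a·V_i + b·Ht_i        (no intercept)

where *a* and *b* reflect the relative cell-type abundances (a ≈ 0.92,
b ≈ 0.08). The model does double duty:

1. **Validation** — fitted â and b̂ near the expected cell frequencies
   confirm that the cell-separated measurements are internally consistent
   with the whole-filament measurements.
2. **Degradation detection** — genes far off the plane carry information.
   The deviation of gene *i* is scored by the *weighted residual*

       R_i = (F_i − a·V_i − b·Ht_i) / ‖(V_i, Ht_i, F_i)‖

   i.e. the residual as a proportion of the gene's overall transcript
   level (Euclidean norm in (V, Ht, F)-space). A large positive R_i means
   the transcript was present in intact filaments but missing from the
   isolated fractions — the signature of transcripts (classically the
   nitrogenase *nif1* cluster) that are rapidly degraded in heterocysts
   during cell separation.

Around this core the package provides the rest of the analysis a
two-cell-type microarray/expression study needs: quantile normalization
and replicate-correlation QC, the low-signal/high-variability gene
filters, Welch-test differential expression with >2-fold & p<0.01 volcano
classification, sample-level PCA, functional-category transcript-share
profiles, a seven-level expression-bin scale, RT-qPCR standard-curve
quantification with cell-specificity estimation, and a ground-truthed
synthetic-data generator for validating all of the above.

## Worked example

```python
from filamix import (SimulationParams, simulate_dataset, reduce_dataset,
                     condition_means, fit_mixture, weighted_residuals,
                     rank_outliers, differential_expression,
                     volcano_classify)

params = SimulationParams(seed=42)          # 5,657 genes, one condition
matrix, truth = simulate_dataset(params)

reduced, report = reduce_dataset(matrix, "P")
v, ht, f = condition_means(reduced, "P")
fit = fit_mixture(v, ht, f, method="ols", n_boot=1000, seed=1)
records = weighted_residuals(fit, v, ht, f, gene_ids=reduced.gene_ids)
top = rank_outliers(records, 10, direction="f_high")
table, counts = volcano_classify(differential_expression(reduced, "P"))

print(f"retained {report.genes_out} of {report.genes_in} genes "
      f"({report.genes_removed_low_signal} low-signal, "
      f"{report.genes_removed_variability} high-variability)")
print(f"a = {fit.a:.3f} (95% CI {fit.bootstrap_ci_a[0]:.3f}-{fit.bootstrap_ci_a[1]:.3f}), "
      f"b = {fit.b:.3f} (95% CI {fit.bootstrap_ci_b[0]:.3f}-{fit.bootstrap_ci_b[1]:.3f})")
hits = sum(g in truth.degraded_genes for g in top.index)
print(f"top 10 f_high outliers contain {hits} of the "
      f"{len(truth.degraded_genes)} degraded transcripts")
print(f"volcano: {counts.up_in_Ht} genes up in heterocysts, "
      f"{counts.up_in_V} up in vegetative cells")
```

Output:

```
retained 4892 of 5657 genes (765 low-signal, 0 high-variability)
a = 0.943 (95% CI 0.931-0.953), b = 0.081 (95% CI 0.077-0.084)
top 10 f_high outliers contain 9 of the 10 degraded transcripts
volcano: 849 genes up in heterocysts, 850 up in vegetative cells
```

Reading: the gene filters removed 765 genes averaging below 128 signal
units; the mixture fit recovered coefficients close to the generating
values a=0.92, b=0.08 (the small upward shift in â is replicate-noise
variance on the most abundant genes); ranking genes by weighted residual
in the `f_high` direction (filament ≫ prediction) put 9 of the 10 planted
heterocyst-degraded transcripts in the top 10; and the volcano
classification recovered the planted ~30% differentially expressed genes
split evenly between cell types.

The same pipeline is scriptable from a shell:

```bash
filamix simulate --seed 42 --out sim/
filamix normalize --in sim/matrix.tsv --out norm.tsv
filamix qc --in norm.tsv --stat r2 --out qc.tsv
filamix fit-mix --in sim/matrix.tsv --condition P --boot 1000 --seed 1 --out fit.json
filamix outliers --fit fit.json --in sim/matrix.tsv --condition P \
    --top 20 --direction f_high --out outliers.tsv
filamix de --in sim/matrix.tsv --condition P --out de.tsv
filamix profile categories --in sim/matrix.tsv --group P_Ht --out cats.tsv
```

Real data in the package's TSV dialect (`gene_id`, `product`, `category`,
then `{P|M|H}_{F|V|Ht}_{replicate}` sample columns) drop straight into the
same commands; `read_expression_table` accepts a sample-name mapping for
foreign headers and `read_geo_series_matrix` ingests GEO series-matrix
text files.

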