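# coexnet

Gene co-expression networks from correlation, mutual-information and
regression association measures — built for comparing how these measures
behave, not just for running one of them.

## The problem

A weighted gene co-expression network assigns each pair of genes *i*, *j*
an adjacency `0 ≤ A_ij ≤ 1` (symmetric, unit diagonal) derived from an
association measure applied to their expression profiles across *m*
samples.  Which measure to use is contested: correlations only see linear
or monotonic relationships; mutual information (MI) sees any dependence but
must be estimated from discretized data, is sensitive to outliers, and is
far more expensive.  This package implements the main contenders behind one
interface so they can be compared on equal footing:

* **Correlations** — Pearson, Spearman, and the robust **biweight
  midcorrelation (bicor)**, which replaces mean/variance with median/MAD
  and down-weights points with a Tukey biweight, `w_i = (1 − u_i²)² 1{|u_i|<1}`
  with `u_i = (x_i − med(x)) / (9 mad(x))`; a `max_p_outliers` cap (default
  0.02) bounds the fraction of zero-weight points per side of the median.
* **MI adjacencies** — expression profiles are discretized into `√m`
  equal-width bins, entropies estimated with the Miller–Madow correction,
  and MI normalized into the symmetric uncertainty
  `ASU_ij = 2 MI_ij / (H_i + H_j)`, or the universal adjacencies
  `AUV1 = ASU/(2 − ASU)` and `AUV2_ij = MI_ij / max(H_i, H_j)`
  (whose complements are universal distance functions).
* **The cor-MI map** — under bivariate normality,
  `AUV2 ≈ F(cor(x,y))` with
  `F(s) = log(1 + ε − s²)/log(ε) · (1 − ω) + ω`, `ω = 0.43 m^−0.30`,
  `ε = ω^2.2`: MI-based adjacencies can be predicted from a correlation at
  a tiny fraction of the cost.
* **Regression R²** — polynomial (default cubic) and truncated-power cubic
  spline fits in both directions, `R² = cor(y, ŷ)²`, symmetrized by
  min/average/max: nonlinear association measures without discretization.
* **Network transforms** — hard threshold, soft thresholds `|cor|^β`
  (unsigned, β=6) and `((1+cor)/2)^β` (signed, β=12), general bounded
  rescaling, and the topological overlap matrix (TOM).
* **MI network inference** — RELNET, CLR, MRNET and ARACNE (data-processing
  inequality pruning).
* **Module detection** — average-linkage clustering of `1 − A` with a
  deterministic branch cut, identical for every measure, evaluated by the
  Rand index against a known partition.
* **Synthetic benchmarks** — a bivariate-normal pair sweep and a
  module-structured generator with linear and quadratic gene–gene
  relationships.

## Worked example

```python
import coexnet as cx

# 200 genes x 200 samples: three modules of 60 genes (+20 background),
# half the members of two modules depend quadratically on the module seed
expr, truth = cx.simulate_module_data(cx.ModuleSimConfig(seed=1))

for meas in ("bicor-signed", "auv2", "spline"):
    labels = cx.modules_pipeline(expr, measure=meas)
    k = len(set(labels) - {0})
    print(f"{meas}: {k} modules, Rand vs truth = {cx.rand_index(truth, labels):.3f}")
```

prints

```
bicor-signed: 5 modules, Rand vs truth = 0.910
auv2: 3 modules, Rand vs truth = 1.000
spline: 3 modules, Rand vs truth = 1.000
```

The signed-correlation network splits each nonlinear module in two — a
quadratic gene is uncorrelated with a linear gene driven by the same seed
profile — while the MI and spline pipelines keep them together.  On
bivariate-normal data the measures instead agree closely:

```python
from coexnet.benchmarks import pair_benchmark
res = pair_benchmark(n_pairs=200, m=1000, seed=1)
print(f"Spearman(AUV1, AUV2) = {res['spearman_auv1_auv2']:.3f}")
print(f"cor-MI prediction MAE = {res['prediction_mae']:.4f}")
print(f"mean |bicor - cor|    = {res['bicor_pearson_mean_absdiff']:.4f}")
```

```
Spearman(AUV1, AUV2) = 1.000
cor-MI prediction MAE = 0.0070
mean |bicor - cor|    = 0.0058
```

i.e. the two universal MI adjacencies are rank-equivalent, the cor-MI map
predicts AUV2 from the correlation to better than 0.01 on average, and
bicor is practically indistinguishable from Pearson under normality.

The same pipelines are available from the shell:

```bash
coexnet simulate modules --seed 1 --out-prefix sim_
coexnet modules --measure auv2 --in sim_expr.tsv --out labels.tsv
coexnet cor --method bicor --in sim_expr.tsv --out bicor.tsv
coexnet infer --method aracne --dpi-tolerance 0.2 --in sim_expr.tsv --out net.tsv
```

Estimator classes (`Correlation`, `MIAdjacency`, `SoftThreshold`, `TOM`,
`HierarchicalModules`, …) follow scikit-learn conventions and compose in a
`Pipeline`; the module-level functions are thin wrappers around them.

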