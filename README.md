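# chemrisk

Reliability-based component selection for chemical-risk classification on
plant-floor sensor data.

Factories that produce pharmaceuticals monitor dozens of channels — volatile
substance concentrations, physicochemical properties, and network-security
telemetry — and must classify the current chemical-hazard level (no / low /
medium / high risk) from heavily imbalanced data. Before classification,
the feature table is usually compressed with PCA-family extraction, and the
perennial question is **how many components to keep and which features
belong to them**. The classical answers (Kaiser's eigenvalue-greater-than-1
rule, the scree-plot elbow) look only at eigenvalues and routinely over- or
under-shoot, which costs classification accuracy.

`chemrisk` implements an alternative: a Cronbach-type **reliability
criterion**. For a scale of `k` standardized features with mean absolute
inter-item correlation `r̄` and mean absolute item–total correlation `ṙ`,

```
β = k·r̄·ṙ / (1 + (k−1)·r̄·ṙ)
```

A feature `i` joins component `m` when `Φ(t_{m,i}) ≥ β`, where `Φ` is the
standard normal CDF and `t` a transform of the component loadings;
multiply-assigned features go to their max-|loading| component, and
components whose member scale fails the reliability criterion are pruned.
A kernel-SVM margin extension handles features inside an ambiguity band
`[β−δ, β+δ]` around the threshold.

The package provides:

* `chemrisk.datagen` — a seeded generator for synthetic hazard tables
  (40,000 × 63 by default: 18 toxic, 28 physicochemical, 17
  network-security channels; class prevalences 12.1 / 4 / 3.5%, remainder
  risk-free; a planted 18-feature informative subspace).
* `chemrisk.extraction` — PCA, centroid-class PCA (CCPCA),
  stochastic-gradient PCA (GPCA) and kernel PCA behind one
  loadings/eigenvalue contract.
* `chemrisk.selection` — Kaiser, scree, fused (K+SP) and β criteria, plus
  the SVM-margin variant and the end-to-end selection pipeline.
* `chemrisk.exposure` — the mixture exposure index
  `Ps = ΣPs_r / ΣNDS_r` over permissible limits, and a configurable
  risk-level ladder.
* `chemrisk.benchmark` — stratified-CV balanced-accuracy comparison of
  pipelines with pairwise Wilcoxon significance marks.
* a thin `chemrisk` CLI (`generate`, `fit`, `select`, `exposure`,
  `benchmark`, `run`).

## Worked example

```python
from chemrisk import GeneratorConfig, generate_dataset, run_selection_pipeline

table, truth = generate_dataset(GeneratorConfig(n_samples=4000, seed=0))
planted = set(truth.informative_set)
for crit in ("k", "sp", "ksp", "beta"):
    sel, model = run_selection_pipeline(table, "pca", crit)
    kept = set(sel.retained_features)
    jac = len(kept & planted) / len(kept | planted)
    print(f"{crit:>5}  M={sel.M_retained}  features={len(kept):2d}  overlap={jac:.3f}")
```

prints

```
    k  M=4  features=52  overlap=0.346
   sp  M=3  features=49  overlap=0.288
  ksp  M=3  features=49  overlap=0.288
 beta  M=4  features=34  overlap=0.368
```

Kaiser (`k`) keeps four components but 52 features, including channels that
are mostly noise; the scree elbow (`sp`) and the fused rule (`ksp`) drop to
three components, losing a small but genuinely discriminant one; the
reliability criterion (`beta`) keeps the four reliable components with 34
features and overlaps the planted informative subspace (Jaccard 0.368) more
closely than any eigenvalue rule. The `examples/` directory has one short
script per capability (generation, selection, exposure index, benchmark).

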