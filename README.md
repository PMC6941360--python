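# dimr — data-integrative Bayesian mixture regression

`dimr` models (log) gene expression as a **mixture of sparse linear
regressions** on regulatory signals — promoter-level transcription-factor
binding and histone-modification scores — while **integrating auxiliary
biological data** (3D-proximity clusters, gene-function flags, expression
profiles, …) into the clustering. It is aimed at regulatory genomicists
who suspect that "one regression for all genes" hides gene-set-specific
regulatory programs, and who hold side data that might say which genes
belong together.

## The model

For genes `i = 1..n` with expression `y_i` and predictors `x_i`:

    y_i | z_i  ~  N(x_i' β_{z_i}, σ²_{z_i}),        K unknown

Component labels `z` carry a similarity-guided conditional prior: with an
`n × n` gene-similarity matrix `S` derived from the auxiliary attributes,

    sp(Z_i = k | z_-i, s, α)  ∝  n*_{-i,k} · h_i(k)     existing component
                              ∝  α                      new component

where `h_i(k) = 1 + Σ_{i'∈k} s_{ii'}` and `n*_{-i,k}` counts members of
`k` whose similarity to gene `i` clears a third-quartile threshold. With
`S = 0` this is exactly the Chinese-restaurant-process prior. Within each
component, coefficients get Bayesian-Lasso shrinkage; coefficients whose
95% credible interval covers zero are reported as exact zeros.

Mixed-type auxiliary attributes are turned into `S` by one of three
measures: **Gower** (match/mismatch + range-normalised distances),
**Wilson** (frequency-difference variant of the heterogeneous value
difference metric), or the frequency-aware **DIMR-S**, which scores genes
sharing a *rare* category (e.g. both flagged for a rare function) as more
similar than genes sharing a common one. Measures and attribute subsets
are compared by H-fold cross-validated prediction error against null and
randomized-attribute baselines and an OLS baseline.

## Worked example

```python
import numpy as np
from dimr import (SamplerConfig, build_matrix, default_scenarios,
                  fit, generate)

ds = generate(default_scenarios()["separable3"], seed=1)   # 300 genes, K=3
S = build_matrix(ds.attributes, "dimrs")                   # similarity
summary = fit(ds.data, S, SamplerConfig(n_iter=400, burn_in=200, seed=7))

print(summary.K_hat)                  # 3
print(np.round(summary.pi_hat, 2))    # [0.35 0.32 0.33]
print(np.round(summary.beta_sparse[0], 2))
# [ 0.    2.94 -1.97  0.    0.    1.47]
```

The fitted number of components matches the simulation truth (K = 3);
`pi_hat` gives the share of genes per component, and each row of
`beta_sparse` is one component's regression law — intercept first, exact
zeros where the 95% credible interval covers 0. Here component 1
recovers the true law `y = 3x₁ − 2x₂ + 1.5x₅` of one simulated gene
set, including its zero pattern. `examples/` walks through the similarity
measures, fitting, cross-validation, model selection and the shell
pipeline (`01_similarity_measures.py` … `05_cli_pipeline.sh`), each
printing a short interpretation of its output.

A thin CLI mirrors the library: `dimr simulate | similarity | fit |
predict | cv | select` (see `dimr --help`).

## Layout

    src/dimr/        attributes, similarity, model, sampler,
                     evaluate, synthetic, io, cli
    tests/           unit, property and acceptance tests
    examples/        runnable narrative scripts
    docs/methods.md  model, priors, algorithms, design choices, limits
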