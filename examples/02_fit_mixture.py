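"""Fit the similarity-guided mixture regression on synthetic data.

Generates the three-component scenario, computes the frequency-aware
similarity matrix from its auxiliary attribute, runs the Gibbs sampler
and prints the estimated number of components, mixture proportions,
per-component noise and sparsified coefficients next to the truth.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from dimr import SamplerConfig, build_matrix, default_scenarios, fit, generate

scenario = default_scenarios()["separable3"]
ds = generate(scenario, seed=1)
S = build_matrix(ds.attributes, "dimrs")

config = SamplerConfig(n_iter=400, burn_in=200, thin=2, seed=7)
summary = fit(ds.data, S, config)

print(f"estimated components K_hat = {summary.K_hat} "
      f"(truth {scenario.K})")
print("mixture proportions:", np.round(summary.pi_hat, 3))
print("component noise SD: ", np.round(np.sqrt(summary.sigma2_mean), 3),
      f"(truth {scenario.sigma[0]})")
ari = adjusted_rand_score(ds.z_true, summary.map_partition)
print(f"adjusted Rand index vs true partition: {ari:.3f}\n")

print("sparsified coefficients (rows = components; zero = the 95%")
print("credible interval covers 0; intercept column first):")
print(np.round(summary.beta_sparse, 2))
print("\ntrue slopes for comparison:")
print(np.column_stack([scenario.intercepts, scenario.beta]))
print("\nComponents are recovered up to label order; within each matched"
      "\nrow the zero pattern and signs should agree with the truth.")
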