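"""Cross-validated benefit of informative auxiliary data.

Runs 5-fold cross-validation of the mixture model under three similarity
sources — the informative attribute, a column-permuted surrogate of it,
and no similarity at all — plus an ordinary least squares baseline, and
prints the aggregated prediction errors.
"""

import numpy as np

from dimr import (SamplerConfig, build_matrix, cross_validate,
                  default_scenarios, generate, ols_baseline,
                  randomize_attributes)

ds = generate(default_scenarios()["separable3"], seed=2)
config = SamplerConfig(n_iter=150, burn_in=75, thin=1, seed=2,
                       summary_iter=120, summary_burn=30)

S_inf = build_matrix(ds.attributes, "dimrs")
S_rnd = build_matrix(randomize_attributes(ds.attributes, seed=99), "dimrs")

# x-only prediction: responsibilities come from the prior weights alone,
# so held-out error reflects what the model knows about a new gene from
# its predictors and attributes (the default mode also conditions on the
# observed test response, which flatters every model; see docs/methods.md)
rows = [
    ("informative", cross_validate(ds.data, S_inf, config, H=5, cv_seed=2,
                                   mode="prior")),
    ("randomized", cross_validate(ds.data, S_rnd, config, H=5, cv_seed=2,
                                  mode="prior")),
    ("null", cross_validate(ds.data, None, config, H=5, cv_seed=2,
                            mode="prior")),
    ("ols", ols_baseline(ds.data, H=5, cv_seed=2)),
]

print(f"{'model':>12}  {'cv_mse':>8}  {'R2':>6}")
for name, res in rows:
    print(f"{name:>12}  {res.cv_mse:8.3f}  {res.r2:6.3f}")

print(
    "\nLower cv_mse is better. The informative similarity routes each"
    "\nheld-out gene to its own component's regression line, so its error"
    "\nis far below the response variance. Randomized and null similarity"
    "\ncarry no gene-level information: their predictions average the"
    "\ncomponent lines, which is no better than the single pooled OLS"
    "\nline on data this heterogeneous."
)
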