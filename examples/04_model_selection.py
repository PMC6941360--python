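"""Rank similarity measures and attribute sets by cross-validated error.

Mirrors the study protocol for choosing the similarity function and the
auxiliary-attribute combination: every (measure, attribute-set) pair is
cross-validated, together with a null model and a randomized baseline
whose replicates are summarised by mean and quartiles.
"""

from dimr import SamplerConfig, default_scenarios, generate, select_model

ds = generate(default_scenarios()["separable3"], seed=3)
config = SamplerConfig(n_iter=120, burn_in=60, thin=1, seed=3,
                       summary_iter=100, summary_burn=25)

# x-only prediction mode: ranks models by what they can say about a
# new gene from predictors and attributes alone (see docs/methods.md)
ranking = select_model(
    ds.data, ds.attributes,
    measures=("dimrs", "gower", "wilson"),
    attribute_sets={"all": ds.attributes.attribute_names},
    config=config, H=5, cv_seed=3, n_randomized=3, mode="prior")

print(ranking.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\nRows are sorted by cross-validated MSE; the top row is the selected"
    "\nmodel. The 'randomized' row averages column-permuted surrogates of"
    "\nthe attribute table (q1/q3 are the quartiles across replicates) and"
    "\nranks near the null model. Note Wilson's score: its categorical"
    "\nrule compares category *frequencies*, so the scenario's three"
    "\nnear-balanced levels all look alike to it and it carries almost no"
    "\ninformation here — one reason to prefer the frequency-aware match"
    "\nmeasure for attributes of this shape."
)
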