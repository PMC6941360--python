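"""Synthetic mixture-of-regressions datasets with auxiliary attributes.

The generator emulates the statistical structure the method targets:

* K latent gene clusters with cluster-specific sparse coefficient
  vectors; responses drawn as ``y_i ~ N(x_i' beta_{z_i}, sigma2_{z_i})``;
* heavy-tailed nonnegative predictors (lognormal, mimicking promoter
  ChIP signal scores) or plain Gaussian predictors;
* mixed-type auxiliary attributes whose agreement with the latent
  clusters is tunable through an informativeness parameter ``rho`` in
  [0, 1]: a categorical attribute takes a cluster-determined level with
  probability ``rho`` and a uniform level otherwise; a continuous
  attribute is a unit-variance Gaussian whose cluster mean shift scales
  with ``rho``; rare Boolean function flags fire with a high probability
  inside one designated cluster and a low background rate elsewhere.

For lognormal predictors the regression truth lives on the *log* scale:
the emitted design ``data.X`` is ``log`` of the raw draws (so true
coefficients are directly comparable to fitted ones), and the raw
heavy-tailed matrix is kept in ``raw_X`` for realistic file output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .attributes import CATEGORICAL, CONTINUOUS, AttributeTable
from .errors import DataError
from .model import RegressionData


@dataclass
class AttributeSpec:
    """One auxiliary attribute of a scenario.

    ``kind`` is ``categorical``, ``continuous`` or ``boolean``. For
    categorical attributes ``levels`` is the number of levels and
    ``rho`` the probability of taking the cluster-determined level. For
    Boolean flags ``p_true_in`` / ``p_true_out`` give the TRUE rate
    inside the designated cluster and elsewhere. ``shift`` scales the
    cluster mean separation of continuous attributes.
    """

    name: str
    kind: str
    levels: int = 2
    rho: float = 0.0
    missing_rate: float = 0.0
    p_true_in: float = 0.3
    p_true_out: float = 0.01
    cluster: int | None = None
    shift: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous", "boolean"):
            raise DataError(f"unknown attribute kind {self.kind!r}")
        if not 0.0 <= self.rho <= 1.0:
            raise DataError("rho must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise DataError("missing_rate must be in [0, 1)")


@dataclass
class ScenarioSpec:
    """Full specification of one synthetic study condition."""

    n: int
    p: int
    K: int
    pi: np.ndarray
    beta: np.ndarray           # K x p (slopes)
    intercepts: np.ndarray     # K
    sigma: np.ndarray          # K noise SDs
    predictor_model: str = "lognormal"   # or "gaussian"
    attributes: list = field(default_factory=list)
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise DataError("mixture weights must sum to 1")
        if self.beta.shape != (self.K, self.p):
            raise DataError("beta must be K x p")
        if self.sigma.size != self.K or (self.sigma <= 0).any():
            raise DataError("sigma must be K positive noise SDs")
        if self.predictor_model not in ("lognormal", "gaussian"):
            raise DataError(
                f"unknown predictor model {self.predictor_model!r}")


@dataclass
class SyntheticDataset:
    """Generated bundle: regression data, attributes and the truth."""

    data: RegressionData
    attributes: AttributeTable
    z_true: np.ndarray
    spec: ScenarioSpec
    raw_X: np.ndarray | None = None


def generate(spec: ScenarioSpec, seed: int | None = None) -> SyntheticDataset:
    """Draw one dataset from a scenario (``seed`` overrides the spec's)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, p, K = spec.n, spec.p, spec.K
    gene_ids = tuple(f"g{i + 1:05d}" for i in range(n))

    z = rng.choice(K, size=n, p=spec.pi)
    raw_X = None
    if spec.predictor_model == "lognormal":
        design = rng.standard_normal((n, p))
        raw_X = np.exp(design)
    else:
        design = rng.standard_normal((n, p))
    y = (spec.intercepts[z] + np.einsum("ij,ij->i", design, spec.beta[z])
         + spec.sigma[z] * rng.standard_normal(n))

    cols, types, zero_levels = {}, {}, {}
    for a_idx, a in enumerate(spec.attributes):
        if a.kind == "continuous":
            offsets = (np.arange(K) - (K - 1) / 2.0)
            vals = a.rho * a.shift * offsets[z] + rng.standard_normal(n)
            cols[a.name] = vals.astype(float)
            types[a.name] = CONTINUOUS
        elif a.kind == "categorical":
            L = max(a.levels, K)
            determined = np.arange(K) % L
            take = rng.random(n) < a.rho
            vals = np.where(take, determined[z], rng.integers(0, L, size=n))
            cols[a.name] = np.array([f"c{v}" for v in vals], dtype=object)
            types[a.name] = CATEGORICAL
        else:  # boolean flag tied to one cluster
            c = a.cluster if a.cluster is not None else a_idx % K
            p_true = np.where(z == c, a.p_true_in, a.p_true_out)
            cols[a.name] = rng.random(n) < p_true
            types[a.name] = CATEGORICAL
            zero_levels[a.name] = False
        if a.missing_rate > 0:
            miss = rng.random(n) < a.missing_rate
            col = pd.Series(cols[a.name], dtype=object)
            col[miss] = np.nan
            cols[a.name] = col.to_numpy()

    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    table = AttributeTable(values, types=types, zero_levels=zero_levels)
    data = RegressionData(y, design, gene_ids,
                          tuple(f"x{j + 1}" for j in range(p)))
    return SyntheticDataset(data=data, attributes=table, z_true=z,
                            spec=spec, raw_X=raw_X)


def _separable3() -> ScenarioSpec:
    beta = np.array([
        [3.0, -2.0, 0.0, 0.0, 1.5],
        [-3.0, 2.0, 1.5, 0.0, 0.0],
        [0.0, 0.0, -2.0, 2.5, 0.0],
    ])
    return ScenarioSpec(
        n=300, p=5, K=3, pi=np.full(3, 1 / 3), beta=beta,
        intercepts=np.array([0.0, 1.0, -1.0]),
        sigma=np.array([0.5, 0.5, 0.5]),
        predictor_model="lognormal",
        attributes=[AttributeSpec(name="func_clust", kind="categorical",
                                  levels=3, rho=0.9)],
        name="separable3")


def _esc_like() -> ScenarioSpec:
    # 5 components, 15 predictors, sparse sign-varied slopes
    rngb = np.random.default_rng(20200102)
    beta = np.zeros((5, 15))
    for k in range(5):
        nz = rngb.choice(15, size=5, replace=False)
        beta[k, nz] = rngb.choice([-1, 1], size=5) * rngb.uniform(0.8, 2.5, 5)
    attrs = [AttributeSpec(name=f"flag_{nm}", kind="boolean", cluster=k,
                           p_true_in=0.25, p_true_out=0.01)
             for k, nm in enumerate(
                 ["maintain", "plurip", "repplurip", "self", "esc_sp"])]
    attrs += [
        AttributeSpec(name="prox_clust", kind="categorical", levels=20,
                      rho=0.85, missing_rate=0.05),
        AttributeSpec(name="eb_profile", kind="continuous", rho=0.7),
        AttributeSpec(name="chr_nr", kind="categorical", levels=19, rho=0.0),
    ]
    return ScenarioSpec(
        n=1000, p=15, K=5,
        pi=np.array([0.18, 0.24, 0.25, 0.15, 0.18]),
        beta=beta, intercepts=np.array([1.0, 0.5, 0.0, -0.5, -1.0]),
        sigma=np.full(5, 0.45), predictor_model="lognormal",
        attributes=attrs, name="esc_like")


def _homogeneous() -> ScenarioSpec:
    return ScenarioSpec(
        n=200, p=5, K=1, pi=np.array([1.0]),
        beta=np.array([[2.0, -1.0, 0.0, 0.5, 0.0]]),
        intercepts=np.array([0.0]), sigma=np.array([0.5]),
        predictor_model="lognormal",
        attributes=[AttributeSpec(name="func_clust", kind="categorical",
                                  levels=3, rho=0.5)],
        name="homogeneous")


def default_scenarios() -> dict:
    """Named registry of standard study conditions.

    ``separable3``: 300 genes, 5 predictors, 3 well-separated components
    with sign-opposed slopes and one rho = 0.9 categorical attribute.
    ``esc_like``: 1000 genes, 15 predictors, 5 components with
    unequal mixture proportions, five rare Boolean function flags
    (~3-10% TRUE), a 20-level proximity-cluster attribute, a continuous
    profile and an uninformative chromosome-number attribute (8 auxiliary
    attributes in total). ``homogeneous``: single-component control.
    """
    return {"separable3": _separable3(), "esc_like": _esc_like(),
            "homogeneous": _homogeneous()}


def with_rho(spec: ScenarioSpec, rho: float) -> ScenarioSpec:
    """Copy of a scenario with every attribute's informativeness set to
    ``rho`` (Boolean flags interpolate their in-cluster TRUE rate)."""
    new_attrs = []
    for a in spec.attributes:
        if a.kind == "boolean":
            new_attrs.append(replace(
                a, p_true_in=a.p_true_out + rho * (0.9 - a.p_true_out)))
        else:
            new_attrs.append(replace(a, rho=rho))
    return replace(spec, attributes=new_attrs)
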