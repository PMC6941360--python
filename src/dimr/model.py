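"""Mixture-of-regressions model and similarity-guided allocation prior.

The observation model is a finite mixture of Gaussian linear regressions:
conditionally on its component label ``z_i``, the (log) expression of
gene ``i`` is ``y_i ~ N(x_i' beta_{z_i}, sigma2_{z_i})``.

Component labels carry a non-exchangeable conditional prior built from an
n x n gene-similarity matrix ``S``::

    sp(Z_i = k | z_-i, s, alpha)  propto  n*_{-i,k} * h_i(k)   (existing k)
                                  propto  alpha                (new component)

where ``n*_{-i,k}`` counts the members of component ``k`` whose similarity
to gene ``i`` reaches a threshold ``T_i``, and
``h_i(k) = 1 + sum_{i' in k} s_{ii'}`` is the overall similarity of gene
``i`` to component ``k``. ``T_i`` is the third quartile of gene ``i``'s
similarities to the co-members of its current cluster, so a gene
gravitates to components where it is highly similar to the majority of
the other genes. With an all-zero ``S``
(and hence ``T_i = 0``) the prior reduces exactly to the Chinese
restaurant process: existing components weighted by size, a new one by
``alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import DataError

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class RegressionData:
    """Response vector and predictor matrix for n genes."""

    y: np.ndarray
    X: np.ndarray
    gene_ids: tuple = ()
    predictor_names: tuple = ()
    standardized: bool = False

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise DataError("X must be n x p with n matching y")
        if not (np.isfinite(self.y).all() and np.isfinite(self.X).all()):
            raise DataError("y and X must be finite with no missing entries")
        if not self.gene_ids:
            self.gene_ids = tuple(f"g{i}" for i in range(self.y.size))
        if not self.predictor_names:
            self.predictor_names = tuple(
                f"x{j + 1}" for j in range(self.X.shape[1]))
        if self.n < self.p:
            warnings.warn("fewer genes than predictors", stacklevel=2)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "RegressionData":
        gid = tuple(np.asarray(self.gene_ids)[idx])
        return RegressionData(self.y[idx], self.X[idx], gid,
                              self.predictor_names, self.standardized)


@dataclass
class MixtureState:
    """Current allocation vector and per-component parameters.

    ``beta`` rows are coefficient vectors on the design scale (including
    any intercept column of the design); labels in ``z`` are contiguous
    integers ``0..K-1`` and every label has a parameter row.
    """

    z: np.ndarray
    beta: np.ndarray        # K x d
    sigma2: np.ndarray      # K
    pi: np.ndarray          # K, sums to 1

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=int)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.sigma2 = np.asarray(self.sigma2, dtype=float).ravel()
        self.pi = np.asarray(self.pi, dtype=float).ravel()
        if (self.sigma2 <= 0).any():
            raise DataError("component variances must be positive")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise DataError("component weights must sum to 1")
        labels = np.unique(self.z)
        if labels.size and (labels.min() < 0
                            or labels.max() >= self.beta.shape[0]):
            raise DataError("labels must index parameter rows")

    @property
    def K(self) -> int:
        return int(np.unique(self.z).size)


@dataclass
class AllocationPriorSpec:
    """Concentration, similarity source and threshold rule for the prior."""

    alpha: float = 1.0
    S: np.ndarray | None = None
    threshold_rule: str = "cluster_q3"  # or "zero"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise DataError("alpha must be positive")
        if self.threshold_rule not in ("cluster_q3", "zero"):
            raise DataError(f"unknown threshold rule {self.threshold_rule!r}")


def component_loglik(y_i, x_i, beta_k, sigma2_k):
    """Log normal density log N(y_i; x_i' beta_k, sigma2_k).

    Broadcasts over components when ``beta_k`` is K x d and ``sigma2_k``
    length K.
    """
    sigma2_k = np.asarray(sigma2_k, dtype=float)
    if np.any(sigma2_k <= 0):
        raise DataError("variance must be positive")
    beta_k = np.asarray(beta_k, dtype=float)
    mu = beta_k @ np.asarray(x_i, dtype=float)
    r = np.asarray(y_i, dtype=float) - mu
    return -0.5 * (_LOG_2PI + np.log(sigma2_k)) - 0.5 * r * r / sigma2_k


def gene_threshold(i: int, members: np.ndarray, S: np.ndarray,
                   q: float = 0.75) -> float:
    """Third quartile of gene ``i``'s similarities to its cluster
    co-members (``members`` may include ``i``; it is excluded).

    The threshold is gene-specific: it gates which co-members count in
    ``n*`` so that a gene gravitates to components where it is highly
    similar to the majority of the other genes. A gene with no
    co-members (singleton cluster) gets threshold 0, so every similarity
    counts and CRP behaviour is recovered. Quantiles interpolate linearly
    at position (m + 1) q (the "weibull" convention), so four values
    0.1..0.4 give 0.375.
    """
    m = np.asarray(members)
    m = m[m != i]
    if m.size == 0:
        return 0.0
    # inlined weibull quantile: np.quantile's dispatch overhead dominates
    # the sampler's inner loop
    s = np.sort(S[i, m])
    h = (s.size + 1) * q - 1.0
    if h <= 0.0:
        return float(s[0])
    if h >= s.size - 1:
        return float(s[-1])
    lo = int(h)
    return float(s[lo] + (h - lo) * (s[lo + 1] - s[lo]))


def threshold(i: int, z: np.ndarray, S: np.ndarray, q: float = 0.75) -> float:
    """Threshold ``T_i``: q3 of gene i's similarities within its cluster."""
    z = np.asarray(z)
    return gene_threshold(i, np.flatnonzero(z == z[i]), S, q)


def allocation_prior(i: int, z: np.ndarray, S: np.ndarray, alpha: float,
                     T_i: float):
    """Conditional allocation prior for gene ``i``.

    Gene ``i`` is excluded from all sums (its entry in ``z`` is ignored).
    Returns ``(labels, weights, new_weight, probs)`` where ``labels`` are
    the existing component labels (ascending), ``weights`` their
    unnormalised prior weights ``n*_{-i,k} h_i(k)``, ``new_weight`` is
    ``alpha``, and ``probs`` the normalised probabilities over existing
    components followed by the new-component slot.
    """
    if alpha <= 0:
        raise DataError("alpha must be positive")
    z = np.asarray(z, dtype=int)
    n = z.size
    mask = np.ones(n, dtype=bool)
    mask[i] = False
    z_rest = z[mask]
    s_rest = S[i][mask]
    labels, inv = np.unique(z_rest, return_inverse=True)
    K = labels.size
    h = 1.0 + np.bincount(inv, weights=s_rest, minlength=K)
    nstar = np.bincount(inv[s_rest >= T_i], minlength=K)
    weights = nstar * h
    c = weights.sum() + alpha
    probs = np.concatenate([weights, [alpha]]) / c
    return labels, weights, float(alpha), probs


def marginal_loglik(data: RegressionData, state: MixtureState) -> float:
    """Mixture log-likelihood sum_i log sum_k pi_k N(y_i; x_i' b_k, s2_k)."""
    mu = data.X @ state.beta.T                       # n x K
    r = data.y[:, None] - mu
    ll = (-0.5 * (_LOG_2PI + np.log(state.sigma2))[None, :]
          - 0.5 * r * r / state.sigma2[None, :])
    keep = state.pi > 0
    return float(np.sum(logsumexp(ll[:, keep], axis=1,
                                  b=state.pi[None, keep])))


def partition_log_prior(z: np.ndarray, S: np.ndarray, alpha: float,
                        q: float = 0.75) -> float:
    """Pseudo log-score sum_i log sp(Z_i = z_i | z_-i, s, alpha).

    Used to rank kept posterior draws when selecting the MAP partition.
    Vectorised over genes; per-gene thresholds are the q3 of the gene's
    own cluster.
    """
    z = np.asarray(z, dtype=int)
    n = z.size
    labels, inv = np.unique(z, return_inverse=True)
    K = labels.size
    M = np.zeros((n, K))
    M[np.arange(n), inv] = 1.0
    T_i = np.zeros(n)
    for k in range(K):
        m = np.flatnonzero(inv == k)
        if m.size < 2:
            continue
        sub = S[np.ix_(m, m)].copy()
        np.fill_diagonal(sub, np.nan)
        T_i[m] = np.nanquantile(sub, q, axis=1, method="weibull")
    H = 1.0 + S @ M - np.diag(S)[:, None] * M          # h_i(k), i excluded
    B = (S >= T_i[:, None]).astype(float)
    Nstar = B @ M - (np.diag(S) >= T_i)[:, None] * M
    W = Nstar * H
    # a singleton's own cluster vanishes when the gene is removed, so the
    # gene sits in the "new component" slot with weight alpha; a gene
    # whose own-cluster weight is 0 under the *current* thresholds (such
    # states are reachable because thresholds move as other genes move)
    # is scored as if it needed a rebirth, also weight alpha
    sizes = np.bincount(inv, minlength=K)
    singleton = sizes[inv] == 1
    own = np.where(singleton, alpha, W[np.arange(n), inv])
    own = np.maximum(own, alpha)
    c = W.sum(axis=1) + alpha
    return float(np.sum(np.log(own) - np.log(c)))
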