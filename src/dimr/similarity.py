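"""Pairwise gene-similarity measures for mixed-type auxiliary attributes.

Three measures are provided, all returning values in [0, 1]:

``gower``
    Gower's general similarity coefficient: exact match (1) / mismatch (0)
    for categorical attributes, range-normalised Manhattan similarity for
    continuous ones. Pairs where either value is missing — or where both
    values sit at a Boolean attribute's "zero" (FALSE) level and double
    zeros are excluded — do not contribute.

``wilson``
    A similarity-based variant of Wilson & Martinez's heterogeneous value
    difference metric without output-class information: categorical
    similarity compares the overall frequencies of the two observed
    categories, 1 - |n_Ai - n_Aj| / n; continuous similarity is
    1 - |A_i - A_j| / (4 sd), clipped below at 0. A missing value yields
    similarity 0 but still counts as a defined comparison.

``dimrs``
    A frequency-aware measure designed for the mixture-regression setting:
    categorical mismatches score 0, matches score
    1 - n_A (n_A - 1) / (n (n - 1)), so that genes sharing a *rare*
    category are more similar than genes sharing a frequent one;
    continuous attributes use the same range-normalised Manhattan
    similarity as Gower.

``null``
    All off-diagonal similarities zero. With this matrix the
    similarity-guided allocation prior reduces exactly to the Chinese
    restaurant process.

Per-attribute similarities are combined across attributes by averaging
over *defined* comparisons; pairs with no defined attribute get overall
similarity 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attributes import CATEGORICAL, CONTINUOUS, AttributeMeta, AttributeTable
from .errors import ConfigurationError, DataError

MEASURES = ("gower", "wilson", "dimrs", "null")


@dataclass
class SimilarityMatrix:
    """Symmetric n x n gene-similarity matrix with provenance."""

    S: np.ndarray
    measure_id: str
    attribute_set: tuple
    gene_ids: tuple = ()
    n_all_undefined: int = 0  # pairs with no defined attribute (set to 0)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise DataError("similarity matrix must be square")

    @property
    def n(self) -> int:
        return self.S.shape[0]

    def subset(self, idx) -> "SimilarityMatrix":
        gid = tuple(np.asarray(self.gene_ids)[idx]) if self.gene_ids else ()
        return SimilarityMatrix(self.S[np.ix_(idx, idx)], self.measure_id,
                                self.attribute_set, gid)


# ----------------------------------------------------------------------
# scalar pair kernels (one attribute, one gene pair)
# ----------------------------------------------------------------------

def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def gower_pair(a_i, a_j, meta: AttributeMeta,
               include_double_zero: bool = True) -> tuple[float, bool]:
    """Gower similarity of one attribute value pair.

    Returns ``(similarity, defined)``. The pair is undefined when either
    value is missing, or when both values equal the attribute's zero
    level and double zeros are excluded.
    """
    if meta is None:
        raise ConfigurationError("attribute metadata required")
    if _is_missing(a_i) or _is_missing(a_j):
        return 0.0, False
    if meta.type == CATEGORICAL:
        if (not include_double_zero and meta.zero_level is not None
                and a_i == meta.zero_level and a_j == meta.zero_level):
            return 0.0, False
        return (1.0 if a_i == a_j else 0.0), True
    if meta.degenerate:
        if a_i == a_j:
            return 1.0, True
        raise DataError(f"attribute {meta.name!r}: zero range but "
                        "unequal values")
    return 1.0 - abs(float(a_i) - float(a_j)) / meta.vrange, True


def wilson_pair(a_i, a_j, meta: AttributeMeta, n: int) -> tuple[float, bool]:
    """Wilson-style similarity of one attribute value pair.

    A missing value gives similarity 0 but a *defined* comparison.
    Continuous similarity is clipped below at 0.
    """
    if _is_missing(a_i) or _is_missing(a_j):
        return 0.0, True
    if meta.type == CATEGORICAL:
        counts = meta.frequencies.counts
        return 1.0 - abs(counts[a_i] - counts[a_j]) / n, True
    if meta.sd == 0:
        raise DataError(f"attribute {meta.name!r}: zero standard deviation")
    s = 1.0 - abs(float(a_i) - float(a_j)) / (4.0 * meta.sd)
    return max(s, 0.0), True


def dimrs_pair(a_i, a_j, meta: AttributeMeta, n: int) -> tuple[float, bool]:
    """Frequency-aware similarity of one attribute value pair.

    Matched categorical values score ``1 - n_A (n_A - 1) / (n (n - 1))``
    where ``n_A`` is the category's count: rare categories yield higher
    similarity. Mismatches score 0 (defined); a missing value makes the
    comparison undefined.
    """
    if n < 2:
        raise DataError("at least two genes required")
    if _is_missing(a_i) or _is_missing(a_j):
        return 0.0, False
    if meta.type == CATEGORICAL:
        if a_i != a_j:
            return 0.0, True
        counts = meta.frequencies.counts
        return 1.0 - counts[a_i] * (counts[a_j] - 1) / (n * (n - 1)), True
    if meta.degenerate:
        if a_i == a_j:
            return 1.0, True
        raise DataError(f"attribute {meta.name!r}: zero range but "
                        "unequal values")
    return 1.0 - abs(float(a_i) - float(a_j)) / meta.vrange, True


def combine(sims, defined) -> float:
    """Average per-attribute similarities over defined comparisons.

    With no defined attribute the combined similarity is 0 (no evidence
    of similarity; avoids a 0/0).
    """
    sims = np.asarray(sims, dtype=float)
    defined = np.asarray(defined, dtype=bool)
    d = defined.sum()
    if d == 0:
        return 0.0
    return float(sims[defined].sum() / d)


# ----------------------------------------------------------------------
# vectorised matrix construction
# ----------------------------------------------------------------------

def _attribute_layers(table: AttributeTable, col: str, measure: str,
                      include_double_zero):
    """(n x n similarity, n x n defined-mask) for one attribute."""
    n = table.n
    meta = table.meta(col)
    missing = table.missing[col].to_numpy()
    obs = ~missing

    if meta.type == CONTINUOUS:
        v = pd.to_numeric(table.values[col], errors="coerce").to_numpy(float)
        if measure == "wilson":
            if meta.sd == 0:
                raise DataError(f"attribute {col!r}: zero standard deviation")
            diff = np.abs(v[:, None] - v[None, :])
            sim = np.clip(1.0 - diff / (4.0 * meta.sd), 0.0, 1.0)
            both = np.outer(obs, obs)
            sim = np.where(both, sim, 0.0)  # missing -> 0, still defined
            return sim, np.ones((n, n), dtype=bool)
        # gower / dimrs share the range-normalised Manhattan similarity
        if meta.degenerate:
            sim = np.ones((n, n))
        else:
            sim = 1.0 - np.abs(v[:, None] - v[None, :]) / meta.vrange
        both = np.outer(obs, obs)
        return np.where(both, sim, 0.0), both

    # categorical
    codes, uniques = pd.factorize(table.values[col][obs])
    full_codes = np.full(n, -1, dtype=int)
    full_codes[obs] = codes
    match = (full_codes[:, None] == full_codes[None, :]) & np.outer(obs, obs)
    counts_map = meta.frequencies.counts
    counts = np.array([counts_map[u] for u in uniques], dtype=float)
    cnt = np.where(obs, counts[np.clip(full_codes, 0, None)], np.nan)

    if measure == "gower":
        exclude = (include_double_zero is False
                   or (include_double_zero is None
                       and meta.zero_level is not None))
        defined = np.outer(obs, obs)
        if exclude and meta.zero_level is not None:
            is_zero = obs & (table.values[col] == meta.zero_level).to_numpy()
            defined &= ~np.outer(is_zero, is_zero)
        return np.where(match & defined, 1.0, 0.0), defined
    if measure == "wilson":
        sim = 1.0 - np.abs(cnt[:, None] - cnt[None, :]) / n
        sim = np.where(np.outer(obs, obs), sim, 0.0)
        return sim, np.ones((n, n), dtype=bool)
    if measure == "dimrs":
        sim = 1.0 - cnt[:, None] * (cnt[None, :] - 1.0) / (n * (n - 1))
        sim = np.where(match, sim, 0.0)
        return sim, np.outer(obs, obs)
    raise ConfigurationError(f"unknown measure {measure!r}")


def build_matrix(table: AttributeTable, measure_id: str,
                 attribute_subset=None,
                 include_double_zero: bool | None = None) -> SimilarityMatrix:
    """Similarity matrix over all gene pairs for a chosen measure.

    Parameters
    ----------
    table
        Auxiliary attribute table.
    measure_id
        One of ``gower``, ``wilson``, ``dimrs``, ``null``.
    attribute_subset
        Attribute names to use; ``None`` means all.
    include_double_zero
        Gower only. ``True``: Boolean FALSE/FALSE pairs count as matches;
        ``False``: such pairs are undefined for attributes with a declared
        zero level; ``None`` (default): exclusion is on for attributes
        with a zero level (Boolean flags) and off otherwise.
    """
    if measure_id not in MEASURES:
        raise ConfigurationError(f"unknown measure {measure_id!r}")
    n = table.n
    gid = tuple(table.gene_ids)
    if measure_id == "null":
        return SimilarityMatrix(np.eye(n), "null", (), gid)
    cols = list(attribute_subset) if attribute_subset is not None \
        else table.attribute_names
    if not cols:
        raise ConfigurationError("attribute subset must be non-empty")
    for c in cols:
        if c not in table.types:
            raise ConfigurationError(f"unknown attribute {c!r}")

    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for c in cols:
        sim, defined = _attribute_layers(table, c, measure_id,
                                         include_double_zero)
        num += np.where(defined, sim, 0.0)
        den += defined
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    n_undef = int(np.sum(den[np.triu_indices(n, 1)] == 0))

    # self-similarity: 1 whenever the gene has any observed attribute
    any_obs = (~table.missing[cols].to_numpy()).any(axis=1)
    np.fill_diagonal(S, np.where(any_obs, 1.0, 0.0))
    S = np.clip(S, 0.0, 1.0)
    S = (S + S.T) / 2.0  # enforce exact symmetry against rounding
    return SimilarityMatrix(S, measure_id, tuple(cols), gid,
                            n_all_undefined=n_undef)


def null_matrix(n: int, gene_ids=()) -> SimilarityMatrix:
    """All-zero off-diagonal similarity (no side information)."""
    return SimilarityMatrix(np.eye(n), "null", (), tuple(gene_ids))


def randomize_attributes(table: AttributeTable, seed: int) -> AttributeTable:
    """Column-wise permutation surrogate of an attribute table.

    Destroys the gene-attribute linkage while preserving each column's
    marginal frequencies; used for the randomised-similarity baseline.
    """
    return table.randomize(seed)
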