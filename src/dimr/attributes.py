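"""Mixed-type auxiliary attribute tables.

An :class:`AttributeTable` holds one row per gene and one column per
auxiliary attribute. Each attribute is declared either ``categorical``
(values are opaque labels; Booleans are two-level categoricals) or
``continuous`` (real-valued). Missing entries are tracked in an explicit
mask and carry no value.

Similarity measures consume the table through per-attribute metadata
(:class:`AttributeMeta`): observed range for continuous attributes,
category frequencies and standard deviations, and the optional "zero
level" of Boolean flags used by Gower's double-zero exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"

#: String tokens recognised as the FALSE level of a Boolean attribute.
_FALSE_TOKENS = {"FALSE", "False", "false", "F", "0"}
_TRUE_TOKENS = {"TRUE", "True", "true", "T", "1"}


@dataclass
class CategoricalFrequencies:
    """Category counts for one categorical attribute.

    ``counts`` maps each observed category to its count ``n_A`` among
    non-missing entries; ``n_obs`` is the number of non-missing entries.
    """

    counts: dict
    n_obs: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_obs:
            raise DataError("category counts must sum to the observed count")
        if any(c < 1 for c in self.counts.values()):
            raise DataError("every observed category must have count >= 1")


@dataclass
class AttributeMeta:
    """Per-attribute metadata needed by the pairwise similarity kernels."""

    name: str
    type: str
    vmin: float | None = None        # continuous: observed min (non-missing)
    vmax: float | None = None        # continuous: observed max
    sd: float | None = None          # continuous: observed SD
    frequencies: CategoricalFrequencies | None = None
    zero_level: object | None = None  # categorical: level treated as "zero"
    degenerate: bool = False          # continuous with vmax == vmin

    @property
    def vrange(self) -> float:
        return float(self.vmax) - float(self.vmin)


class AttributeTable:
    """n genes x M mixed-type auxiliary attributes with a missingness mask.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID. Continuous columns must be numeric
        (NaN allowed); categorical columns may hold any hashable labels.
    types
        Mapping column name -> ``"categorical"`` | ``"continuous"``.
        Columns absent from the mapping are inferred: numeric dtype ->
        continuous, otherwise categorical.
    missing
        Optional boolean DataFrame aligned with ``values``; ``True`` marks
        a missing entry. NaN values are always treated as missing.
    zero_levels
        Mapping column name -> level treated as the categorical "zero"
        (used by Gower's double-zero exclusion). Boolean columns default
        to ``False`` as their zero level.
    """

    def __init__(self, values: pd.DataFrame, types: dict | None = None,
                 missing: pd.DataFrame | None = None,
                 zero_levels: dict | None = None):
        if values.index.has_duplicates:
            raise DataError("duplicate gene IDs in attribute table")
        self.values = values.copy()
        types = dict(types or {})
        self.types: dict = {}
        for col in values.columns:
            if col in types:
                t = types[col]
                if t not in (CATEGORICAL, CONTINUOUS):
                    raise ConfigurationError(
                        f"attribute {col!r}: unknown type {t!r}")
            else:
                t = CONTINUOUS if pd.api.types.is_numeric_dtype(
                    values[col]) and values[col].dtype != bool else CATEGORICAL
            self.types[col] = t

        miss = pd.DataFrame(False, index=values.index, columns=values.columns)
        if missing is not None:
            miss |= missing.reindex(index=values.index,
                                    columns=values.columns).fillna(False)
        for col in values.columns:
            miss[col] |= values[col].isna()
        self.missing = miss

        self.zero_levels = dict(zero_levels or {})
        for col, t in self.types.items():
            if t == CATEGORICAL and col not in self.zero_levels:
                obs = self._observed(col)
                labels = set(obs.unique().tolist())
                if labels and labels <= ({True, False} | _FALSE_TOKENS
                                         | _TRUE_TOKENS):
                    false_like = labels & ({False} | _FALSE_TOKENS)
                    if false_like:
                        self.zero_levels[col] = next(iter(false_like))

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def m(self) -> int:
        return len(self.values.columns)

    @property
    def attribute_names(self) -> list:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def _observed(self, col: str) -> pd.Series:
        return self.values[col][~self.missing[col]]

    def frequencies(self, col: str) -> CategoricalFrequencies:
        if self.types[col] != CATEGORICAL:
            raise ConfigurationError(f"{col!r} is not categorical")
        obs = self._observed(col)
        counts = obs.value_counts().to_dict()
        return CategoricalFrequencies(counts=counts, n_obs=int(obs.size))

    def meta(self, col: str) -> AttributeMeta:
        """Metadata for one attribute, computed over the full table.

        Ranges, SDs and frequencies are fixed side information derived
        once from all non-missing entries; they are not recomputed when
        rows are subset (e.g. per CV fold).
        """
        if col not in self.types:
            raise ConfigurationError(f"unknown attribute {col!r}")
        t = self.types[col]
        if t == CONTINUOUS:
            obs = pd.to_numeric(self._observed(col))
            if obs.empty:
                raise DataError(f"attribute {col!r} has no observed values")
            vmin, vmax = float(obs.min()), float(obs.max())
            sd = float(obs.std(ddof=0))
            return AttributeMeta(name=col, type=t, vmin=vmin, vmax=vmax,
                                 sd=sd, degenerate=(vmax == vmin))
        return AttributeMeta(name=col, type=t,
                             frequencies=self.frequencies(col),
                             zero_level=self.zero_levels.get(col))

    def subset_rows(self, gene_ids) -> "AttributeTable":
        return AttributeTable(self.values.loc[gene_ids], types=self.types,
                              missing=self.missing.loc[gene_ids],
                              zero_levels=self.zero_levels)

    def randomize(self, seed: int) -> "AttributeTable":
        """Independently permute each column (values and missingness
        together), destroying gene-attribute linkage while preserving
        every column's marginal distribution."""
        rng = np.random.default_rng(seed)
        new_vals = self.values.copy()
        new_miss = self.missing.copy()
        for col in self.values.columns:
            perm = rng.permutation(self.n)
            new_vals[col] = self.values[col].to_numpy()[perm]
            new_miss[col] = self.missing[col].to_numpy()[perm]
        return AttributeTable(new_vals, types=self.types, missing=new_miss,
                              zero_levels=self.zero_levels)
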