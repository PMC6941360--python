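"""Delimited-table input/output, ID alignment and run manifests.

All tables are plain delimited text (tab or comma, auto-detected from
the file extension: ``.csv`` means comma, everything else tab) with a
header row and a gene-ID column. Gene IDs are opaque strings; alignment
between the expression/predictor table and the attribute table is by ID,
never by row order. A sidecar YAML schema declares each attribute
column's type, the missing-value token (default ``NA``) and optional
categorical zero levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attributes import CATEGORICAL, CONTINUOUS, AttributeTable
from .errors import ConfigurationError, DataError
from .evaluate import EvaluationResult
from .model import RegressionData
from .sampler import LassoHyper, PosteriorSummary, SamplerConfig
from .similarity import SimilarityMatrix

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """One-file description of a full run, loadable from YAML.

    Groups the input paths, the sampler settings and the evaluation
    settings; every referenced path is checked to exist at load time,
    and the seed ends up in every output artifact's manifest.
    """

    data: str | None = None
    attributes: str | None = None
    schema: str | None = None
    similarity: str | None = None
    out: str | None = None
    response: str = "y"
    alpha: float = 1.0
    iters: int = 2000
    burn_in: int = 1000
    thin: int = 2
    seed: int = 0
    standardize: bool = True
    lasso_r: float = 1.0
    lasso_delta: float = 0.1
    include_double_zero: bool | None = None
    folds: int = 5
    measures: tuple = ("dimrs", "gower", "wilson")
    attribute_sets: dict = field(default_factory=dict)
    randomized_replicates: int = 50
    log_level: str = "INFO"

    def sampler_config(self) -> SamplerConfig:
        return SamplerConfig(n_iter=self.iters, burn_in=self.burn_in,
                             thin=self.thin, seed=self.seed,
                             alpha=self.alpha,
                             lasso=LassoHyper(r=self.lasso_r,
                                              delta=self.lasso_delta),
                             standardize=self.standardize)


def load_run_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    if "measures" in raw:
        raw["measures"] = tuple(raw["measures"])
    rc = RunConfig(**raw)
    for key in ("data", "attributes", "schema", "similarity"):
        val = getattr(rc, key)
        if val is not None and not Path(val).exists():
            raise ConfigurationError(f"{path}: {key} path {val!r} not found")
    return rc


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path, id_column: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), dtype={id_column: str})
    if id_column not in df.columns:
        raise DataError(f"{path}: missing ID column {id_column!r}")
    if df[id_column].duplicated().any():
        dup = df[id_column][df[id_column].duplicated()].iloc[0]
        raise DataError(f"{path}: duplicate gene ID {dup!r}")
    return df.set_index(id_column)


def read_schema(path) -> dict:
    """Load a YAML attribute schema.

    Layout::

        id_column: gene_id        # optional, default gene_id
        missing_token: NA         # optional
        delimiter: "\t"         # optional override of the extension rule
        columns:
          func_clust: {type: categorical}
          eb_profile: {type: continuous}
          flag_self:  {type: categorical, zero: "False"}
    """
    with open(path) as fh:
        schema = yaml.safe_load(fh) or {}
    if "columns" not in schema:
        raise ConfigurationError(f"{path}: schema must declare 'columns'")
    return schema


def read_attribute_table(path, schema: dict | str | None = None
                         ) -> AttributeTable:
    """Read an attribute table, applying a schema if given."""
    if isinstance(schema, (str, Path)):
        schema = read_schema(schema)
    schema = schema or {}
    id_col = schema.get("id_column", "gene_id")
    token = str(schema.get("missing_token", "NA"))
    sep = schema.get("delimiter") or _sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str,
                     keep_default_na=False)
    if id_col not in df.columns:
        raise DataError(f"{path}: missing ID column {id_col!r}")
    df = df.set_index(id_col)
    missing = (df == token) | (df == "")
    df = df.mask(missing, np.nan)

    types, zero_levels = {}, {}
    for col, decl in (schema.get("columns") or {}).items():
        if col not in df.columns:
            raise ConfigurationError(f"schema column {col!r} not in table")
        types[col] = decl.get("type", CATEGORICAL)
        if "zero" in decl:
            zero_levels[col] = str(decl["zero"])
    for col in df.columns:
        t = types.get(col)
        if t is None:
            # no declaration: numeric-looking columns become continuous
            try:
                pd.to_numeric(df[col].dropna())
                t = CONTINUOUS
            except (ValueError, TypeError):
                t = CATEGORICAL
            types[col] = t
        if t == CONTINUOUS:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = df[col][pd.to_numeric(df[col],
                                            errors="coerce").isna()
                              & df[col].notna()]
                row = bad.index[0] if len(bad) else "?"
                raise DataError(
                    f"column {col!r}, row {row!r}: not numeric") from exc
    return AttributeTable(df, types=types, missing=missing,
                          zero_levels=zero_levels)


def read_regression_data(path, response: str,
                         id_column: str = "gene_id") -> RegressionData:
    """Read a table holding the response column and all predictors."""
    df = _read_table(path, id_column)
    if response not in df.columns:
        raise DataError(f"{path}: missing response column {response!r}")
    X = df.drop(columns=[response]).apply(
        lambda col: pd.to_numeric(col, errors="coerce"))
    y = pd.to_numeric(df[response], errors="coerce")
    if y.isna().any() or X.isna().any().any():
        bad_cols = [c for c in X.columns if X[c].isna().any()]
        if y.isna().any():
            bad_cols = [response] + bad_cols
        raise DataError("missing or non-numeric values in column(s) "
                        f"{bad_cols}")
    return RegressionData(y.to_numpy(), X.to_numpy(),
                          tuple(df.index), tuple(X.columns))


def align(data: RegressionData, table: AttributeTable, logger=None):
    """Join regression data and attributes on gene ID.

    Genes present in only one of the two tables are dropped; the dropped
    count is logged. Row order follows the regression table.
    """
    d_ids = pd.Index(data.gene_ids)
    common = d_ids.intersection(table.gene_ids)
    if common.empty:
        raise DataError("no overlapping gene IDs between tables")
    dropped = (len(d_ids) - len(common)) + (len(table.gene_ids) - len(common))
    if dropped and logger is not None:
        logger.warning("dropped %d genes absent from one table", dropped)
    keep = d_ids.isin(common)
    idx = np.flatnonzero(keep)
    data2 = data.subset(idx)
    table2 = table.subset_rows(list(np.asarray(data2.gene_ids)))
    return data2, table2, int(dropped)


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------

def write_similarity(sim: SimilarityMatrix, path) -> None:
    ids = list(sim.gene_ids) or [f"g{i}" for i in range(sim.n)]
    df = pd.DataFrame(sim.S, index=ids, columns=ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=_sep(path), float_format=FLOAT_FMT)


def read_similarity(path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return SimilarityMatrix(df.to_numpy(float), "custom", (),
                            tuple(df.index))


def write_dataset(ds, out_dir) -> None:
    """Write a synthetic dataset as the delimited tables the fit reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = list(ds.data.gene_ids)
    main = pd.DataFrame({"y": ds.data.y}, index=pd.Index(ids, name="gene_id"))
    for j, nm in enumerate(ds.data.predictor_names):
        main[nm] = ds.data.X[:, j]
    main.to_csv(out / "data.tsv", sep="\t", float_format=FLOAT_FMT)

    vals = ds.attributes.values.copy()
    vals = vals.mask(ds.attributes.missing, "NA")
    vals.index.name = "gene_id"
    vals.to_csv(out / "attributes.tsv", sep="\t", float_format=FLOAT_FMT)

    schema = {"id_column": "gene_id", "missing_token": "NA", "columns": {}}
    for col, t in ds.attributes.types.items():
        decl = {"type": t}
        if col in ds.attributes.zero_levels:
            decl["zero"] = str(ds.attributes.zero_levels[col])
        schema["columns"][col] = decl
    with open(out / "schema.yaml", "w") as fh:
        yaml.safe_dump(schema, fh, sort_keys=True)

    truth = pd.DataFrame({"component": ds.z_true + 1},
                         index=pd.Index(ids, name="gene_id"))
    truth.to_csv(out / "truth.tsv", sep="\t")


def write_results(summary: PosteriorSummary,
                  eval_result: EvaluationResult | None, out_dir,
                  config: dict | None = None) -> dict:
    """Write partition, coefficient, trace and evaluation tables.

    Returns the run manifest (also written as ``manifest.json``). The
    coefficient table round-trips exactly: re-reading it reproduces the
    sparsified zeros.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    part = pd.DataFrame({"gene_id": list(summary.gene_ids),
                         "component": summary.map_partition + 1})
    part.to_csv(out / "partition.tsv", sep="\t", index=False)

    rows = []
    for k in range(summary.K_hat):
        for j, nm in enumerate(summary.predictor_names):
            rows.append({
                "component": k + 1, "predictor": nm,
                "mean": summary.beta_mean[k, j],
                "ci_lo": summary.beta_ci[k, j, 0],
                "ci_hi": summary.beta_ci[k, j, 1],
                "sparse": summary.beta_sparse[k, j]})
    pd.DataFrame(rows).to_csv(out / "coefficients.tsv", sep="\t",
                              index=False, float_format=FLOAT_FMT)

    comp = pd.DataFrame({
        "component": np.arange(summary.K_hat) + 1,
        "pi_hat": summary.pi_hat,
        "sigma2": summary.sigma2_mean,
        "r2": (summary.component_r2 if summary.component_r2 is not None
               else np.full(summary.K_hat, np.nan))})
    comp.to_csv(out / "components.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT)

    if summary.trace_loglik is not None:
        tr = pd.DataFrame({"loglik": summary.trace_loglik,
                           "K": summary.trace_K})
        tr.to_csv(out / "trace.tsv", sep="\t", index=False,
                  float_format=FLOAT_FMT)

    if eval_result is not None:
        ev = pd.DataFrame({"fold": np.arange(eval_result.fold_mse.size) + 1,
                           "mse": eval_result.fold_mse})
        ev["aggregate_mse"] = eval_result.cv_mse
        ev["r2"] = eval_result.r2
        ev.to_csv(out / "fold_mse.tsv", sep="\t", index=False,
                  float_format=FLOAT_FMT)

    manifest = {"package": "dimr", "version": __version__,
                "seed": summary.seed, "K_hat": int(summary.K_hat),
                "n_genes": len(summary.gene_ids),
                "alpha": summary.alpha,
                "config": config or {}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
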