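"""Readers and writers for the long-format MCT tables.

Three plain CSV files describe a trial:

* ``volumes.csv`` — columns ``model_id,mouse_id,arm,day,volume_mm3``, one row
  per mouse per measurement day (unbalanced series are simply absent rows);
* ``covariates.csv`` — columns ``model_id,cancer_type`` plus any additional
  model-level covariate columns;
* ``expression.csv`` (optional) — first column ``gene_id``, one column per
  model_id, log2-scale expression values.
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd

from .datamodel import ARMS, GrowthCurve, MCTDataset
from .exceptions import SchemaError, ValidationError

VOLUME_COLUMNS = ["model_id", "mouse_id", "arm", "day", "volume_mm3"]
COVARIATE_COLUMNS = ["model_id", "cancer_type"]


def _check_columns(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_mct(
    volume_table_path,
    covariate_table_path,
    expression_path: Optional[str] = None,
) -> MCTDataset:
    """Read a validated :class:`MCTDataset` from CSV files.

    Rows are grouped into per-mouse curves and sorted by day; row order and
    surrounding whitespace in the files are irrelevant.
    """
    vol = pd.read_csv(
        volume_table_path, skipinitialspace=True, float_precision="round_trip"
    )
    vol.columns = [str(c).strip() for c in vol.columns]
    _check_columns(vol, VOLUME_COLUMNS, volume_table_path)
    # covariates are read as text ("NA" is a legitimate category label, not
    # a missing value); numeric-looking columns are converted afterwards
    cov = pd.read_csv(covariate_table_path, skipinitialspace=True, dtype=str,
                      keep_default_na=False)
    cov.columns = [str(c).strip() for c in cov.columns]
    _check_columns(cov, COVARIATE_COLUMNS, covariate_table_path)
    for col in cov.columns:
        if col in ("model_id", "cancer_type"):
            continue
        try:
            cov[col] = pd.to_numeric(cov[col])
        except (ValueError, TypeError):
            pass

    for col in ("model_id", "mouse_id", "arm"):
        vol[col] = vol[col].astype(str).str.strip()
    bad_arm = set(vol["arm"]) - set(ARMS)
    if bad_arm:
        raise ValidationError(f"unknown arm value(s): {sorted(bad_arm)}")
    if (vol["volume_mm3"] < 0).any():
        raise ValidationError("negative volume in volume table")
    dup = vol.duplicated(subset=["model_id", "mouse_id", "day"])
    if dup.any():
        row = vol[dup].iloc[0]
        raise ValidationError(
            f"duplicate measurement for mouse {row.mouse_id!r} at day {row.day}"
        )

    curves = []
    for (model_id, mouse_id), grp in vol.groupby(["model_id", "mouse_id"], sort=True):
        grp = grp.sort_values("day")
        arms = grp["arm"].unique()
        if len(arms) != 1:
            raise ValidationError(f"mouse {mouse_id!r} appears in multiple arms")
        curves.append(
            GrowthCurve(
                mouse_id=mouse_id,
                model_id=model_id,
                arm=arms[0],
                days=tuple(int(d) for d in grp["day"]),
                volumes=tuple(float(v) for v in grp["volume_mm3"]),
            )
        )

    cov["model_id"] = cov["model_id"].astype(str).str.strip()
    if cov["model_id"].duplicated().any():
        raise ValidationError("duplicate model_id in covariate table")
    model_covariates = {
        row["model_id"]: {
            k: row[k] for k in cov.columns if k != "model_id"
        }
        for _, row in cov.iterrows()
    }

    expression = None
    if expression_path is not None:
        expr = pd.read_csv(
            expression_path, skipinitialspace=True, float_precision="round_trip"
        )
        expr.columns = [str(c).strip() for c in expr.columns]
        if expr.columns[0] != "gene_id":
            raise SchemaError(f"{expression_path}: first column must be 'gene_id'")
        expression = expr.set_index("gene_id")
        expression.columns = [str(c).strip() for c in expression.columns]

    return MCTDataset(
        curves=curves, model_covariates=model_covariates, expression=expression
    )


def write_mct(dataset: MCTDataset, directory, prefix: str = "") -> dict:
    """Write a dataset to ``volumes.csv``/``covariates.csv``[/``expression.csv``].

    Returns the mapping of table name to written path. Round-trips with
    :func:`read_mct`.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {}

    vol_path = os.path.join(directory, prefix + "volumes.csv")
    dataset.to_long().to_csv(vol_path, index=False)
    paths["volumes"] = vol_path

    cov_cols = ["model_id", "cancer_type"]
    for covs in dataset.model_covariates.values():
        for k in covs:
            if k not in cov_cols:
                cov_cols.append(k)
    cov_rows = [
        {"model_id": m, **covs} for m, covs in dataset.model_covariates.items()
    ]
    cov_path = os.path.join(directory, prefix + "covariates.csv")
    pd.DataFrame(cov_rows, columns=cov_cols).to_csv(cov_path, index=False)
    paths["covariates"] = cov_path

    if dataset.expression is not None:
        expr_path = os.path.join(directory, prefix + "expression.csv")
        out = dataset.expression.copy()
        out.index.name = "gene_id"
        out.to_csv(expr_path)
        paths["expression"] = expr_path

    return paths
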