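"""Readers and writers for the delimited-text formats of the workflow.

All tables travel as TSV by default ("NA" or empty cells = missing); the
dialect is configurable.  Factor roles for the sample annotation (which
columns are technical batches, which are biological, which is the replicate
group) are declared in a small YAML file, since annotation TSVs carry no
role metadata themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .model import (
    LONG_COLUMNS,
    FeatureAnnotation,
    IntegrityError,
    SampleAnnotation,
    validate_long,
)


@dataclass
class Dialect:
    sep: str = "\t"
    na_tokens: tuple = ("NA", "")


def _read(path, dialect: Dialect) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path,
            sep=dialect.sep,
            na_values=list(dialect.na_tokens),
            keep_default_na=False,
            dtype=object,
        )
    except pd.errors.ParserError as exc:  # re-raise with file context
        raise IntegrityError(f"malformed delimited file {path}: {exc}") from exc


def read_long(
    path,
    dialect: Dialect | None = None,
    feature_col: str = "feature_id",
    sample_col: str = "sample_id",
    intensity_col: str = "intensity",
) -> pd.DataFrame:
    """Read a long (feature, sample, intensity) table; NA rows become absent."""
    dialect = dialect or Dialect()
    raw = _read(path, dialect)
    for col in (feature_col, sample_col, intensity_col):
        if col not in raw.columns:
            raise IntegrityError(f"{path}: missing required column '{col}'")
    out = raw.rename(
        columns={feature_col: "feature_id", sample_col: "sample_id", intensity_col: "intensity"}
    ).loc[:, list(LONG_COLUMNS)]
    try:
        out["intensity"] = out["intensity"].astype(float)
    except ValueError as exc:
        raise IntegrityError(f"{path}: non-numeric intensity value ({exc})") from exc
    out = out.loc[out["intensity"].notna()].reset_index(drop=True)
    return validate_long(out)


def write_long(table: pd.DataFrame, path, dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    validate_long(table).to_csv(path, sep=dialect.sep, index=False, na_rep="NA")


def read_wide(path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read a wide matrix TSV: first column feature_id, remaining = samples."""
    dialect = dialect or Dialect()
    raw = _read(path, dialect)
    wide = raw.set_index(raw.columns[0])
    wide = wide.astype(float)
    wide.index.name = "feature_id"
    wide.columns.name = "sample_id"
    if wide.index.duplicated().any():
        raise IntegrityError(f"{path}: duplicate feature_id rows")
    return wide


def write_wide(wide: pd.DataFrame, path, dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    wide.to_csv(path, sep=dialect.sep, na_rep="NA", index_label="feature_id")


def read_sample_annotation(
    path,
    roles: dict | str | None = None,
    dialect: Dialect | None = None,
) -> SampleAnnotation:
    """Read a sample annotation TSV plus a factor-role declaration.

    *roles* is either a mapping or a path to a YAML file with keys
    ``batch_factors`` (list), ``bio_factors`` (list, optional) and
    ``replicate_group`` (column name, optional).
    """
    dialect = dialect or Dialect()
    raw = _read(path, dialect)
    if "run_order" not in raw.columns:
        raise IntegrityError(f"{path}: missing 'run_order' column")
    raw["run_order"] = raw["run_order"].astype(float)
    if not np.all(raw["run_order"] == raw["run_order"].astype(int)):
        raise IntegrityError(f"{path}: run_order must be integers")
    raw["run_order"] = raw["run_order"].astype(int)
    if isinstance(roles, (str, bytes)) or hasattr(roles, "read_text"):
        with open(roles) as fh:
            roles = yaml.safe_load(fh)
    roles = roles or {}
    return SampleAnnotation(
        raw,
        batch_factors=list(roles.get("batch_factors", [])),
        bio_factors=list(roles.get("bio_factors", [])),
        replicate_group=roles.get("replicate_group"),
    )


def write_sample_annotation(ann: SampleAnnotation, path, roles_path=None,
                            dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    ann.frame.to_csv(path, sep=dialect.sep, index=False, na_rep="NA")
    if roles_path is not None:
        with open(roles_path, "w") as fh:
            yaml.safe_dump(
                {
                    "batch_factors": list(ann.batch_factors),
                    "bio_factors": list(ann.bio_factors),
                    "replicate_group": ann.replicate_group,
                },
                fh,
            )


def read_feature_annotation(path, dialect: Dialect | None = None) -> FeatureAnnotation:
    dialect = dialect or Dialect()
    raw = _read(path, dialect)
    if "is_spike_in" in raw.columns:
        raw["is_spike_in"] = raw["is_spike_in"].map(
            {"True": True, "False": False, "1": True, "0": False, True: True, False: False}
        )
        if raw["is_spike_in"].isna().any():
            raise IntegrityError(f"{path}: is_spike_in must be boolean")
    return FeatureAnnotation(raw)


def write_feature_annotation(fann: FeatureAnnotation, path, dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    fann.frame.to_csv(path, sep=dialect.sep, index=False, na_rep="NA")
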