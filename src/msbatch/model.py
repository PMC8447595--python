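"""Shared data structures for the batch-effect adjustment workflow.

The exchange currency between all stages is a *long measurement table*: a
:class:`pandas.DataFrame` with columns ``feature_id``, ``sample_id`` and
``intensity`` holding log2-scale abundances.  Missing values are represented
as *absent rows* (never sentinel zeros — imputed zeros corrupt every
diagnostic downstream), and the wide counterpart uses NaN cells.

Sample metadata travels in a :class:`SampleAnnotation`: one row per sample
with a dense 1-based running order, one column per technical batch factor
(e.g. MS batch, digestion batch), optional biological factors and an optional
replicate-group label.  Feature metadata (peptide -> protein, spike-in flag)
travels in a :class:`FeatureAnnotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LONG_COLUMNS = ("feature_id", "sample_id", "intensity")


class IntegrityError(ValueError):
    """A table violates one of the structural invariants."""


def validate_long(table: pd.DataFrame, annotation: "SampleAnnotation | None" = None) -> pd.DataFrame:
    """Validate a long measurement table and return it (column-normalised).

    Checks: required columns, unique (feature, sample) pairs, finite
    intensities, and — when *annotation* is given — that every sample id is
    annotated.
    """
    missing_cols = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing_cols:
        raise IntegrityError(f"long table is missing columns: {missing_cols}")
    table = table.loc[:, list(LONG_COLUMNS)]
    dup = table.duplicated(subset=["feature_id", "sample_id"])
    if dup.any():
        first = table.loc[dup.idxmax(), ["feature_id", "sample_id"]]
        raise IntegrityError(
            "duplicate (feature_id, sample_id) pair: "
            f"({first['feature_id']}, {first['sample_id']})"
        )
    vals = table["intensity"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = table.loc[~np.isfinite(vals)].iloc[0]
        raise IntegrityError(
            f"non-finite intensity for ({bad['feature_id']}, {bad['sample_id']}); "
            "missing values must be absent rows, not NaN/inf"
        )
    if annotation is not None:
        unknown = set(table["sample_id"]) - set(annotation.sample_ids)
        if unknown:
            raise IntegrityError(f"samples not present in annotation: {sorted(unknown)[:5]}")
    return table


def make_long(feature_id, sample_id, intensity) -> pd.DataFrame:
    """Assemble and validate a long table from three aligned sequences."""
    return validate_long(
        pd.DataFrame(
            {
                "feature_id": np.asarray(feature_id, dtype=object),
                "sample_id": np.asarray(sample_id, dtype=object),
                "intensity": np.asarray(intensity, dtype=float),
            }
        )
    )


def long_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long table to a features x samples matrix (NaN = missing)."""
    if len(table) == 0:
        return pd.DataFrame(dtype=float)
    wide = table.pivot(index="feature_id", columns="sample_id", values="intensity")
    wide.index.name = "feature_id"
    wide.columns.name = "sample_id"
    return wide


def wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt a features x samples matrix to a long table, dropping NaN cells."""
    if wide.size == 0:
        return pd.DataFrame(columns=list(LONG_COLUMNS)).astype({"intensity": float})
    stacked = wide.stack(future_stack=True).dropna()
    out = stacked.rename("intensity").reset_index()
    out.columns = list(LONG_COLUMNS)
    return validate_long(out)


def log_transform(table: pd.DataFrame, base: float = 2.0, offset: float = 0.0) -> pd.DataFrame:
    """log-transform raw-scale intensities: ``log_base(x + offset)``.

    Raises on any non-positive value after the offset (naming the offending
    feature/sample) because downstream stages assume a log scale.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    table = validate_long(table)
    shifted = table["intensity"].to_numpy(dtype=float) + offset
    bad = shifted <= 0
    if bad.any():
        row = table.loc[np.flatnonzero(bad)[0]]
        raise ValueError(
            f"non-positive intensity after offset for ({row['feature_id']}, {row['sample_id']})"
        )
    out = table.copy()
    out["intensity"] = np.log(shifted) / np.log(base)
    return out


@dataclass
class SampleAnnotation:
    """Per-sample metadata: running order, technical and biological factors.

    Parameters
    ----------
    frame:
        One row per sample with at least ``sample_id`` and ``run_order``
        columns plus one column per declared factor.
    batch_factors:
        Names of technical factor columns (e.g. ``MS_batch``).
    bio_factors:
        Names of biological factor columns (e.g. ``diet``).
    replicate_group:
        Optional column name; samples sharing a non-null value are replicate
        injections of the same biospecimen.
    """

    frame: pd.DataFrame
    batch_factors: list[str]
    bio_factors: list[str] = field(default_factory=list)
    replicate_group: str | None = None

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("sample_id", "run_order"):
            if col not in f.columns:
                raise IntegrityError(f"sample annotation is missing the '{col}' column")
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise IntegrityError(f"duplicate sample_id: {dup}")
        order = f["run_order"].to_numpy()
        if pd.isna(order).any():
            raise IntegrityError("run_order contains missing values")
        if not np.array_equal(order, order.astype(int)):
            raise IntegrityError("run_order must be integer ranks")
        if len(np.unique(order)) != len(order):
            raise IntegrityError("run_order values must be unique (resolve ties before import)")
        if order.astype(int).min() < 1:
            raise IntegrityError("run_order is a 1-based rank")
        declared = list(self.batch_factors) + list(self.bio_factors)
        if self.replicate_group is not None:
            declared.append(self.replicate_group)
        for col in declared:
            if col not in f.columns:
                raise IntegrityError(f"declared factor '{col}' is not a column of the annotation")
        for col in self.batch_factors:
            if f[col].isna().any():
                raise IntegrityError(f"batch factor '{col}' has missing levels")
        self.frame = f.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.frame["sample_id"])

    def column(self, name: str) -> pd.Series:
        """A column of the annotation indexed by sample_id."""
        return self.frame.set_index("sample_id")[name]

    def batch_of(self, batch_factor: str) -> pd.Series:
        if batch_factor not in self.frame.columns:
            raise KeyError(f"unknown batch factor '{batch_factor}'")
        return self.column(batch_factor)

    def subset(self, sample_ids) -> "SampleAnnotation":
        keep = self.frame["sample_id"].isin(set(sample_ids))
        return SampleAnnotation(
            self.frame.loc[keep].copy(),
            list(self.batch_factors),
            list(self.bio_factors),
            self.replicate_group,
        )


@dataclass
class FeatureAnnotation:
    """Per-feature metadata: parent protein and spike-in flag."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("feature_id", "protein_id"):
            if col not in f.columns:
                raise IntegrityError(f"feature annotation is missing the '{col}' column")
        if "is_spike_in" not in f.columns:
            f = f.assign(is_spike_in=False)
        if f["feature_id"].duplicated().any():
            dup = f.loc[f["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise IntegrityError(f"duplicate feature_id: {dup}")
        f = f.copy()
        f["is_spike_in"] = f["is_spike_in"].astype(bool)
        self.frame = f.reset_index(drop=True)

    @property
    def feature_ids(self) -> list:
        return list(self.frame["feature_id"])

    def protein_of(self) -> pd.Series:
        return self.frame.set_index("feature_id")["protein_id"]

    def spike_ins(self) -> list:
        return list(self.frame.loc[self.frame["is_spike_in"], "feature_id"])
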