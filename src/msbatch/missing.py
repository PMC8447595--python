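"""Batch-coupled missingness: quantify, filter, and (reluctantly) impute.

Missing values in quantitative proteomics are frequently batch-specific,
and complete-matrix methods (PCA, clustering, ComBat, PVCA) either fail on
them or — worse — attribute zero-filled holes to the batch factor.  The
tools here quantify missingness per feature and batch, filter features by
completeness (overall or per batch, the latter being the ComBat
prerequisite), and gate imputation behind an explicit, warned, mask-tracked
call.  Avoid imputation where possible, or perform it only after batch
correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import SampleAnnotation, long_to_wide, validate_long, wide_to_long


def missingness_by_batch(
    table: pd.DataFrame,
    annotation: SampleAnnotation,
    batch_factor: str,
    flag_margin: float = 0.2,
) -> pd.DataFrame:
    """Observed/possible counts per feature x batch plus a coupling flag.

    ``batch_coupled`` is True when the feature's missing fraction differs
    between batches by more than ``flag_margin``.
    """
    table = validate_long(table, annotation)
    batch = annotation.batch_of(batch_factor)
    n_per_batch = batch.value_counts()
    features = pd.unique(table["feature_id"])
    obs = (
        table.assign(_batch=table["sample_id"].map(batch))
        .groupby(["feature_id", "_batch"], sort=False)["sample_id"]
        .count()
    )
    rows = []
    for feat in features:
        fracs = {}
        for b, n_possible in n_per_batch.items():
            n_obs = int(obs.get((feat, b), 0))
            frac = 1.0 - n_obs / n_possible
            fracs[b] = frac
            rows.append(
                dict(
                    feature_id=feat,
                    batch=b,
                    n_observed=n_obs,
                    n_possible=int(n_possible),
                    fraction_missing=frac,
                )
            )
        spread = max(fracs.values()) - min(fracs.values())
        for r in rows[-len(n_per_batch):]:
            r["batch_coupled"] = bool(spread > flag_margin)
    return pd.DataFrame(rows)


def completeness_filter(
    table: pd.DataFrame,
    min_fraction: float,
    scope: str = "overall",
    annotation: SampleAnnotation | None = None,
    batch_factor: str | None = None,
) -> tuple[pd.DataFrame, int]:
    """Retain features observed in >= ``min_fraction`` of samples.

    ``scope='overall'`` counts across all samples; ``scope='per_batch'``
    requires the fraction in *every* batch (with ``min_fraction > 0`` this
    guarantees the ComBat completeness precondition).  Returns the filtered
    table and the number of removed features.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    table = validate_long(table, annotation)
    features = pd.unique(table["feature_id"])
    if scope == "overall":
        n_samples = (
            len(annotation.sample_ids) if annotation is not None else table["sample_id"].nunique()
        )
        counts = table.groupby("feature_id")["sample_id"].count()
        keep = counts.index[counts / n_samples >= min_fraction]
    elif scope == "per_batch":
        if annotation is None or batch_factor is None:
            raise ValueError("per_batch scope needs annotation and batch_factor")
        batch = annotation.batch_of(batch_factor)
        n_per_batch = batch.value_counts()
        obs = (
            table.assign(_batch=table["sample_id"].map(batch))
            .groupby(["feature_id", "_batch"])["sample_id"]
            .count()
            .unstack(fill_value=0)
            .reindex(columns=n_per_batch.index, fill_value=0)
        )
        frac = obs / n_per_batch
        keep = frac.index[(frac >= min_fraction).all(axis=1)]
    else:
        raise ValueError("scope must be 'overall' or 'per_batch'")
    keep_set = set(keep)
    out = table.loc[table["feature_id"].isin(keep_set)].reset_index(drop=True)
    return out, int(len(features) - len(keep_set))


IMPUTE_POLICIES = ("zero", "global_min", "feature_min", "small_noise")


def impute(
    table: pd.DataFrame,
    policy: str,
    seed: int | None = None,
    annotation: SampleAnnotation | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill all missing cells under an explicit policy; returns (table, mask).

    The sample universe is the annotation's samples when given, else the
    samples present in the table; the feature universe is the table's
    features.  The mask is a long frame (feature_id, sample_id) of exactly
    the imputed cells, so downstream QC can exclude them.  Policies:

    * ``zero`` — 0.0 on the log2 scale (the classic hazard);
    * ``global_min`` — the global observed minimum;
    * ``feature_min`` — the feature's observed minimum;
    * ``small_noise`` — uniform draws from [global_min - 1, global_min]
      (log2), seeded (seed is mandatory for reproducibility).
    """
    if policy not in IMPUTE_POLICIES:
        raise ValueError(f"unknown imputation policy '{policy}'")
    if policy == "small_noise" and seed is None:
        raise ValueError("small_noise imputation requires a seed")
    table = validate_long(table, annotation)
    warnings.warn(
        f"imputing missing values with policy '{policy}': imputation can "
        "introduce batch- or feature-specific bias; avoid it, or perform it "
        "after batch correction",
        UserWarning,
        stacklevel=2,
    )
    wide = long_to_wide(table)
    if annotation is not None:
        wide = wide.reindex(columns=annotation.sample_ids)
    missing = wide.isna()
    if policy == "zero":
        filled = wide.fillna(0.0)
    elif policy == "global_min":
        filled = wide.fillna(float(np.nanmin(wide.to_numpy())))
    elif policy == "feature_min":
        filled = wide.apply(lambda row: row.fillna(row.min()), axis=1)
    else:  # small_noise
        rng = np.random.default_rng(seed)
        gmin = float(np.nanmin(wide.to_numpy()))
        vals = wide.to_numpy(dtype=float).copy()
        holes = np.isnan(vals)
        vals[holes] = rng.uniform(gmin - 1.0, gmin, size=int(holes.sum()))
        filled = pd.DataFrame(vals, index=wide.index, columns=wide.columns)
    mask = missing.stack(future_stack=True)
    mask = mask[mask].reset_index().iloc[:, :2]
    mask.columns = ["feature_id", "sample_id"]
    return wide_to_long(filled), mask
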