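"""Sample-wide normalization: bring all samples onto a common scale.

Normalization aligns per-sample intensity distributions (medians, or full
quantile profiles) before any feature-level batch correction.  The choice of
method is the analyst's: median centering is the mildest (only medians are
aligned), quantile normalization equalises entire distributions and suits
homogeneous cohorts, z-transformation additionally equalises variances.
The library never auto-selects a method.

All normalizers operate on the long table (log2 scale), preserve the
missingness pattern exactly, and validate their preconditions loudly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import validate_long


def _per_sample_groups(table: pd.DataFrame):
    return table.groupby("sample_id", sort=False)["intensity"]


def normalize_median(table: pd.DataFrame) -> pd.DataFrame:
    """Median centering: shift each sample so all medians equal the median of
    per-sample medians (M).  Re-anchoring at M (not 0) keeps the absolute
    log2 scale interpretable for downstream CV computation.
    """
    table = validate_long(table)
    if len(table) == 0:
        return table
    medians = _per_sample_groups(table).median()
    target = float(medians.median())
    shift = table["sample_id"].map(medians)
    out = table.copy()
    out["intensity"] = table["intensity"] - shift + target
    return out


def normalize_quantile(table: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization with missing-value support.

    Complete data reduces to the classic per-rank-mean scheme: each sample's
    sorted vector is replaced by the vector of cross-sample rank means.  With
    missing values, the reference distribution is the per-rank mean of the
    samples' interpolated quantile functions evaluated on a common grid of
    ``m`` probabilities (``m`` = largest per-sample observation count), and
    each observed value maps to the reference quantile at its within-sample
    fractional rank (average ranks for ties).  Missing stays missing.
    """
    table = validate_long(table).reset_index(drop=True)
    groups = dict(tuple(_per_sample_groups(table)))
    if len(groups) < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    counts = {s: len(v) for s, v in groups.items()}
    if min(counts.values()) < 2:
        bad = min(counts, key=counts.get)
        raise ValueError(f"sample '{bad}' has fewer than 2 observed values")
    m = max(counts.values())
    grid = np.linspace(0.0, 1.0, m)
    reference = np.zeros(m)
    for vals in groups.values():
        reference += np.quantile(vals.to_numpy(dtype=float), grid)
    reference /= len(groups)

    out = table.copy()
    new_vals = np.empty(len(table))
    for sample, vals in groups.items():
        n_s = len(vals)
        frac = (vals.rank(method="average").to_numpy() - 1.0) / (n_s - 1.0)
        new_vals[table.index.get_indexer(vals.index)] = np.interp(frac, grid, reference)
    out["intensity"] = new_vals
    return out


def normalize_zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample z-transformation: (x - mean) / sd, sd with n-1 denominator."""
    table = validate_long(table)
    g = _per_sample_groups(table)
    counts = g.count()
    if (counts < 2).any():
        bad = counts.index[counts < 2][0]
        raise ValueError(f"sample '{bad}' has fewer than 2 observed values")
    means = g.mean()
    sds = g.std(ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise ValueError(f"sample '{bad}' has zero standard deviation")
    out = table.copy()
    out["intensity"] = (
        table["intensity"] - table["sample_id"].map(means)
    ) / table["sample_id"].map(sds)
    return out


NORMALIZERS = {
    "median": normalize_median,
    "quantile": normalize_quantile,
    "zscore": normalize_zscore,
}


def normalize(table: pd.DataFrame, method: str) -> pd.DataFrame:
    """Dispatch by method name ('median' | 'quantile' | 'zscore')."""
    if method not in NORMALIZERS:
        raise ValueError(f"unknown normalization method '{method}'")
    return NORMALIZERS[method](table)
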