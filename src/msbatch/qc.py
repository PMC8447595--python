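"""Quality control: correlation-based negative and positive controls.

Whether adjustment removed bias (negative control) and retained or improved
signal (positive control) is judged by proximity metrics that need no
external ground truth:

* sample correlations, stratified into replicate / within-batch /
  between-batch pairs — replicates should correlate highest, and the
  within-vs-between gap should shrink after correction;
* peptide correlations, stratified into same-protein / different-protein
  pairs — unrelated peptides should correlate near zero after correction
  while same-protein peptides stay positively correlated;
* coefficients of variation of raw-scale intensities across replicates,
  binned by abundance, which should decrease.

"Improved clustering by biology" and "more differential hits" are
deliberately not computed: they are subjective and can reward
overcorrection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FeatureAnnotation, SampleAnnotation, long_to_wide, validate_long


@dataclass
class CorrelationSummary:
    """Pairwise correlation coefficients stratified by pair category."""

    coefficients: dict  # category -> np.ndarray of Pearson r
    n_excluded_pairs: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for cat, vals in self.coefficients.items():
            vals = np.asarray(vals, dtype=float)
            rec = {"category": cat, "n_pairs": len(vals)}
            if len(vals):
                rec.update(
                    median=float(np.median(vals)),
                    q1=float(np.quantile(vals, 0.25)),
                    q3=float(np.quantile(vals, 0.75)),
                    mean=float(vals.mean()),
                )
            else:
                rec.update(median=np.nan, q1=np.nan, q3=np.nan, mean=np.nan)
            rows.append(rec)
        return pd.DataFrame(rows)

    def median(self, category: str) -> float:
        vals = self.coefficients.get(category, np.array([]))
        return float(np.median(vals)) if len(vals) else np.nan

    def mean(self, category: str) -> float:
        vals = self.coefficients.get(category, np.array([]))
        return float(np.mean(vals)) if len(vals) else np.nan


def sample_correlation_summary(
    table: pd.DataFrame,
    annotation: SampleAnnotation,
    batch_factor: str,
    min_overlap: int = 50,
) -> CorrelationSummary:
    """Pearson r of every sample pair, classified replicate / within_batch /
    between_batch.

    Correlations use pairwise-complete features; pairs sharing fewer than
    ``min_overlap`` features are excluded and counted.
    """
    table = validate_long(table, annotation)
    wide = long_to_wide(table)
    samples = [s for s in annotation.sample_ids if s in wide.columns]
    wide = wide[samples]
    corr = wide.corr(method="pearson", min_periods=min_overlap)
    present = wide.notna().astype(float)
    overlap = present.T @ present

    batch = annotation.batch_of(batch_factor)
    rep = (
        annotation.column(annotation.replicate_group)
        if annotation.replicate_group
        else pd.Series(index=samples, dtype=object)
    )
    cats: dict[str, list] = {"replicate": [], "within_batch": [], "between_batch": []}
    excluded = 0
    for a, b in itertools.combinations(samples, 2):
        if overlap.loc[a, b] < min_overlap or pd.isna(corr.loc[a, b]):
            excluded += 1
            continue
        r = float(corr.loc[a, b])
        ra, rb = rep.get(a), rep.get(b)
        if pd.notna(ra) and ra == rb:
            cats["replicate"].append(r)
        elif batch[a] == batch[b]:
            cats["within_batch"].append(r)
        else:
            cats["between_batch"].append(r)
    return CorrelationSummary(
        {k: np.asarray(v) for k, v in cats.items()}, n_excluded_pairs=excluded
    )


def _pair_pearson(X: np.ndarray, pairs: np.ndarray, min_overlap: int = 3) -> np.ndarray:
    """Pearson r for given feature-index pairs over pairwise-complete samples."""
    out = np.full(len(pairs), np.nan)
    for k, (i, j) in enumerate(pairs):
        xi, xj = X[i], X[j]
        ok = ~(np.isnan(xi) | np.isnan(xj))
        if ok.sum() < min_overlap:
            continue
        a, b = xi[ok], xj[ok]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        if denom > 0:
            out[k] = float((a * b).sum() / denom)
    return out


def peptide_correlation_summary(
    table: pd.DataFrame,
    features: FeatureAnnotation,
    max_pairs: int = 10000,
    seed: int = 0,
    min_overlap: int = 3,
) -> CorrelationSummary:
    """Pearson r of peptide pairs, same-protein vs different-protein.

    All same-protein pairs are evaluated; different-protein pairs are
    subsampled to ``max_pairs`` with the given seed.
    """
    table = validate_long(table)
    wide = long_to_wide(table)
    protein = features.protein_of()
    feats = [f for f in wide.index if f in protein.index]
    wide = wide.loc[feats]
    prot = protein.loc[feats].to_numpy()
    by_protein: dict = {}
    for idx, p in enumerate(prot):
        by_protein.setdefault(p, []).append(idx)
    same_pairs = [
        (i, j)
        for members in by_protein.values()
        if len(members) > 1
        for i, j in itertools.combinations(members, 2)
    ]
    if not same_pairs:
        raise ValueError("no protein with more than one mapped peptide")

    rng = np.random.default_rng(seed)
    n = len(feats)
    diff_pairs: set = set()
    n_total_pairs = n * (n - 1) // 2
    target = min(max_pairs, max(n_total_pairs - len(same_pairs), 0))
    max_tries = 20 * max(target, 1)
    tries = 0
    while len(diff_pairs) < target and tries < max_tries:
        i, j = rng.integers(0, n, size=2)
        tries += 1
        if i == j or prot[i] == prot[j]:
            continue
        diff_pairs.add((min(i, j), max(i, j)))

    X = wide.to_numpy(dtype=float)
    same_r = _pair_pearson(X, np.asarray(same_pairs), min_overlap)
    diff_r = _pair_pearson(X, np.asarray(sorted(diff_pairs)), min_overlap)
    return CorrelationSummary(
        {
            "same_protein": same_r[~np.isnan(same_r)],
            "different_protein": diff_r[~np.isnan(diff_r)],
        }
    )


def cv_by_abundance(
    table: pd.DataFrame,
    annotation: SampleAnnotation,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-feature coefficient of variation across replicate injections.

    CV = sd/mean of *unlogged* intensities within each replicate group
    (ratio scale), averaged over groups with >= 2 observed values; features
    are binned by mean log10 raw abundance.  Returns one row per feature
    with columns feature_id, mean_log10_abundance, bin, cv.
    """
    if not annotation.replicate_group:
        raise ValueError("annotation declares no replicate_group")
    table = validate_long(table, annotation)
    rep = annotation.column(annotation.replicate_group)
    groups = rep.dropna()
    counts = groups.value_counts()
    if (counts < 2).all():
        raise ValueError("no replicate group with >= 2 samples")
    raw = table.copy()
    raw["raw"] = np.exp2(raw["intensity"])
    raw["rep_group"] = raw["sample_id"].map(groups)

    sub = raw.dropna(subset=["rep_group"])
    g = sub.groupby(["feature_id", "rep_group"])["raw"]
    stats = g.agg(["count", "mean", "std"])
    stats = stats[stats["count"] >= 2]
    stats["cv"] = stats["std"] / stats["mean"]
    cv = stats.groupby("feature_id")["cv"].mean()

    abundance = raw.groupby("feature_id")["raw"].mean()
    out = pd.DataFrame(
        {
            "feature_id": cv.index,
            "mean_log10_abundance": np.log10(abundance.loc[cv.index].to_numpy()),
            "cv": cv.to_numpy(),
        }
    ).reset_index(drop=True)
    out["bin"] = pd.cut(out["mean_log10_abundance"], bins=n_bins, labels=False)
    return out


def qc_compare(
    before: pd.DataFrame,
    after: pd.DataFrame,
    annotation: SampleAnnotation,
    features: FeatureAnnotation,
    batch_factor: str,
    pvca_factors: list[str] | None = None,
    min_overlap: int = 50,
    max_pairs: int = 10000,
    seed: int = 0,
) -> dict:
    """Paired QC report for an adjustment: metrics before vs after + deltas.

    Negative control: batch-linked metrics (within-vs-between correlation
    gap, PVCA batch fraction, spurious different-protein correlation) should
    shrink.  Positive control: replicate and same-protein correlations
    should hold or improve and replicate CVs should drop.
    Requires identical (feature, sample) universes.
    """
    from .diagnostics import pvca  # local import to avoid a cycle

    before = validate_long(before, annotation)
    after = validate_long(after, annotation)
    key_b = set(map(tuple, before[["feature_id", "sample_id"]].to_numpy()))
    key_a = set(map(tuple, after[["feature_id", "sample_id"]].to_numpy()))
    if key_b != key_a:
        raise ValueError(
            "before/after tables cover different (feature, sample) universes "
            f"({len(key_b ^ key_a)} mismatched cells)"
        )

    factors = (
        pvca_factors
        if pvca_factors is not None
        else list(annotation.batch_factors) + list(annotation.bio_factors)
    )

    def metrics(tab: pd.DataFrame) -> dict:
        sc = sample_correlation_summary(tab, annotation, batch_factor, min_overlap)
        pc = peptide_correlation_summary(tab, features, max_pairs=max_pairs, seed=seed)
        out = {
            "sample_correlation": sc,
            "peptide_correlation": pc,
            "median_replicate_r": sc.median("replicate"),
            "median_within_batch_r": sc.median("within_batch"),
            "median_between_batch_r": sc.median("between_batch"),
            "within_between_gap": sc.median("within_batch") - sc.median("between_batch"),
            "mean_same_protein_r": pc.mean("same_protein"),
            "mean_different_protein_r": pc.mean("different_protein"),
        }
        if factors:
            res = pvca(tab, annotation, factors)
            out["pvca"] = res
            out["pvca_batch_fraction"] = float(
                sum(res.proportions.get(f, 0.0) for f in annotation.batch_factors if f in factors)
            )
        if annotation.replicate_group:
            cv = cv_by_abundance(tab, annotation)
            out["cv_table"] = cv
            out["median_cv"] = float(cv["cv"].median())
        return out

    m_before = metrics(before)
    m_after = metrics(after)
    scalar_keys = [
        k for k, v in m_before.items() if isinstance(v, (int, float)) and k in m_after
    ]
    deltas = {k: m_after[k] - m_before[k] for k in scalar_keys}
    return {"before": m_before, "after": m_after, "delta": deltas}
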