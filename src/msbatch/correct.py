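"""Feature-level batch effect correction.

Large MS experiments show two kinds of feature-level bias: a *continuous*
signal drift over running order (LC/MS performance degradation between
instrument cleanings) and *discrete* per-batch shifts.  The two-step
procedure implemented here removes them in sequence:

1. :func:`correct_drift` — per feature and per batch, fit a LOESS curve of
   intensity against running order and subtract it, re-anchoring each
   feature x batch at its median so that only the discrete offsets remain.
2. :func:`center_discrete` (median/mean centering) or :func:`combat`
   (empirical-Bayes location-scale adjustment) — remove the residual
   per-batch shifts.

:func:`adjust_two_step` chains them and records provenance.  Correction is
performed at whatever feature level the input table carries (fragment,
peptide or protein); peptide or fragment level is recommended since protein
inference consumes those abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loess import TooFewPoints, fit_loess
from .model import SampleAnnotation, validate_long

SMALL_BATCH_WARNING_SIZE = 25


@dataclass
class DriftFit:
    """Fitted drift curve for one feature in one batch."""

    feature_id: str
    batch: str
    span: float
    fitted: dict  # run_order -> fitted log2 intensity at observed orders
    n_points: int
    fallback: bool = False  # True when too few points for a curve


def _joined(table: pd.DataFrame, annotation: SampleAnnotation, batch_factor: str) -> pd.DataFrame:
    table = validate_long(table, annotation).reset_index(drop=True)
    batches = annotation.batch_of(batch_factor)
    orders = annotation.column("run_order")
    out = table.copy()
    out["_batch"] = table["sample_id"].map(batches)
    out["_order"] = table["sample_id"].map(orders)
    return out


def _warn_small_batches(annotation: SampleAnnotation, batch_factor: str) -> list[str]:
    sizes = annotation.frame.groupby(batch_factor)["sample_id"].count()
    small = sizes.index[sizes < SMALL_BATCH_WARNING_SIZE].tolist()
    if small:
        warnings.warn(
            f"batch factor '{batch_factor}' has batches smaller than "
            f"{SMALL_BATCH_WARNING_SIZE} samples ({small}); curve fitting and "
            "location/scale estimates in small batches risk over-correction",
            UserWarning,
            stacklevel=3,
        )
    return [str(b) for b in small]


def correct_drift(
    table: pd.DataFrame,
    annotation: SampleAnnotation,
    batch_factor: str,
    span: float = 0.75,
    degree: int = 2,
    min_points: int = 8,
) -> tuple[pd.DataFrame, list[DriftFit]]:
    """Remove continuous signal drift per feature and per batch.

    For every (feature, batch) with at least ``min_points`` observations a
    LOESS curve over running order is fit and subtracted; the corrected
    values are re-anchored so that the feature x batch median is preserved
    exactly, leaving a purely discrete batch structure for step two.
    Batches with fewer observations are left unchanged and recorded as
    fallbacks.
    """
    joined = _joined(table, annotation, batch_factor)
    _warn_small_batches(annotation, batch_factor)
    values = joined["intensity"].to_numpy(dtype=float).copy()
    fits: list[DriftFit] = []
    for (feature, batch), grp in joined.groupby(["feature_id", "_batch"], sort=False):
        ord_idx = np.argsort(grp["_order"].to_numpy())
        rows = grp.index.to_numpy()[ord_idx]
        x = grp["_order"].to_numpy(dtype=float)[ord_idx]
        y = values[rows]
        try:
            fitted = fit_loess(x, y, span=span, degree=degree, min_points=min_points)
        except TooFewPoints:
            fits.append(
                DriftFit(feature, str(batch), span, {}, n_points=len(y), fallback=True)
            )
            continue
        resid = y - fitted
        # anchor so that the per-feature-per-batch median is preserved exactly
        corrected = resid + (np.median(y) - np.median(resid))
        values[rows] = corrected
        fits.append(
            DriftFit(
                feature,
                str(batch),
                span,
                dict(zip((int(v) for v in x), fitted)),
                n_points=len(y),
            )
        )
    out = joined.loc[:, ["feature_id", "sample_id"]].copy()
    out["intensity"] = values
    return out, fits


def drift_fits_frame(fits: list[DriftFit]) -> pd.DataFrame:
    """Flatten DriftFit records to a (feature_id, batch, run_order, fitted) table."""
    rows = []
    for f in fits:
        if f.fallback:
            continue
        for order, val in f.fitted.items():
            rows.append((f.feature_id, f.batch, order, val))
    return pd.DataFrame(rows, columns=["feature_id", "batch", "run_order", "fitted"])


def center_discrete(
    table: pd.DataFrame,
    annotation: SampleAnnotation,
    batch_factor: str,
    stat: str = "median",
) -> pd.DataFrame:
    """Remove discrete per-batch shifts by median (or mean) centering.

    Per feature, every batch's location statistic is moved onto the
    feature's global statistic; features absent from a batch are corrected
    only where observed.  Robust to missing values (the key advantage over
    complete-matrix methods).
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    joined = _joined(table, annotation, batch_factor)
    global_stat = joined.groupby("feature_id")["intensity"].transform(stat)
    batch_stat = joined.groupby(["feature_id", "_batch"])["intensity"].transform(stat)
    out = joined.loc[:, ["feature_id", "sample_id"]].copy()
    out["intensity"] = joined["intensity"] - batch_stat + global_stat
    return out


@dataclass
class CombatParams:
    """All estimated quantities of the parametric EB location-scale model.

    Indices: features g (rows of the per-batch frames), batches b (columns).
    """

    batches: list
    stand_mean: pd.DataFrame  # feature x sample standardization mean
    var_pooled: pd.Series  # per-feature pooled variance
    gamma_hat: pd.DataFrame  # raw per-batch location estimates
    delta_hat: pd.DataFrame  # raw per-batch scale estimates
    gamma_bar: pd.Series  # per-batch location prior mean
    tau_sq: pd.Series  # per-batch location prior variance
    a_prior: pd.Series  # per-batch inverse-gamma shape
    b_prior: pd.Series  # per-batch inverse-gamma scale
    gamma_star: pd.DataFrame  # EB-shrunk locations
    delta_star: pd.DataFrame  # EB-shrunk variances
    n_iter: dict = field(default_factory=dict)
    tol: float = 1.0e-4


def _aprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def combat(
    table: pd.DataFrame,
    annotation: SampleAnnotation,
    batch_factor: str,
    covariates: list[str] | None = None,
    conv: float = 1.0e-4,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, CombatParams]:
    """Parametric empirical-Bayes location-scale batch correction.

    Per feature the model is ``y = alpha + X beta + gamma_b + delta_b eps``:
    features are standardized against grand mean (plus optional categorical
    covariate effects, protecting biological contrasts) and pooled variance;
    per-batch locations (gamma) and scales (delta^2) are estimated and shrunk
    toward a normal / inverse-gamma prior by iterating the conditional
    posterior means; the adjusted data are back-transformed.

    Every feature must be observed in every batch (missing cells within a
    batch are tolerated, whole-batch absence is not), and every batch needs
    at least 2 samples.
    """
    joined = _joined(table, annotation, batch_factor)
    wide = joined.pivot(index="feature_id", columns="sample_id", values="intensity")
    samples = list(wide.columns)
    batch_of = annotation.batch_of(batch_factor)
    batch_labels = pd.Series([batch_of[s] for s in samples], index=samples)
    batches = list(pd.unique(batch_labels))
    if len(batches) < 2:
        raise ValueError("ComBat needs at least 2 batches")
    sizes = batch_labels.value_counts()
    small = sizes.index[sizes < 2].tolist()
    if small:
        raise ValueError(f"batches with fewer than 2 samples: {small}")
    if wide.shape[0] < 2:
        raise ValueError("EB shrinkage needs at least 2 features")
    _warn_small_batches(annotation.subset(samples), batch_factor)

    Y = wide.to_numpy(dtype=float)  # features x samples, NaN = missing
    obs = ~np.isnan(Y)
    # completeness precondition: every feature observed in every batch
    offending = []
    batch_masks = {b: (batch_labels == b).to_numpy() for b in batches}
    for b, mask in batch_masks.items():
        absent = obs[:, mask].sum(axis=1) == 0
        offending += [(wide.index[i], b) for i in np.flatnonzero(absent)]
    if offending:
        raise ValueError(
            "ComBat requires every feature to be observed in every batch; "
            f"offending (feature, batch) pairs: {offending[:10]}"
            + ("..." if len(offending) > 10 else "")
            + " — apply completeness_filter(per_batch) first"
        )

    # design: full batch one-hot + optional covariate dummies (reference-coded)
    B = np.column_stack([batch_masks[b].astype(float) for b in batches])
    if covariates:
        cov_frame = annotation.frame.set_index("sample_id").loc[samples, list(covariates)]
        C = pd.get_dummies(cov_frame.astype(str), drop_first=True).to_numpy(dtype=float)
    else:
        C = np.empty((len(samples), 0))
    X = np.hstack([B, C])
    n_batch = len(batches)

    G, S = Y.shape
    stand_mean = np.zeros_like(Y)
    var_pooled = np.zeros(G)
    Z = np.full_like(Y, np.nan)
    for g in range(G):
        o = obs[g]
        beta, *_ = np.linalg.lstsq(X[o], Y[g, o], rcond=None)
        n_gb = np.array([obs[g, batch_masks[b]].sum() for b in batches], dtype=float)
        grand = float(n_gb @ beta[:n_batch] / n_gb.sum())
        sm = grand + (C @ beta[n_batch:] if C.shape[1] else 0.0)
        stand_mean[g] = sm
        resid = Y[g, o] - X[o] @ beta
        var_pooled[g] = float((resid**2).sum() / o.sum())
        if var_pooled[g] <= 0:
            raise ValueError(f"feature '{wide.index[g]}' has zero pooled variance")
        Z[g] = (Y[g] - stand_mean[g]) / np.sqrt(var_pooled[g])

    gamma_hat = np.zeros((G, n_batch))
    delta_hat = np.zeros((G, n_batch))
    n_obs_gb = np.zeros((G, n_batch))
    for j, b in enumerate(batches):
        Zb = Z[:, batch_masks[b]]
        n_obs_gb[:, j] = (~np.isnan(Zb)).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gamma_hat[:, j] = np.nanmean(Zb, axis=1)
            delta_hat[:, j] = np.nanvar(Zb, axis=1, ddof=1)
    if np.any(n_obs_gb < 2):
        g, j = np.argwhere(n_obs_gb < 2)[0]
        raise ValueError(
            f"feature '{wide.index[g]}' has fewer than 2 observations in batch "
            f"'{batches[j]}'; scale estimation is impossible"
        )

    gamma_bar = gamma_hat.mean(axis=0)
    tau_sq = gamma_hat.var(axis=0, ddof=1)
    a_prior = np.array([_aprior(delta_hat[:, j]) for j in range(n_batch)])
    b_prior = np.array([_bprior(delta_hat[:, j]) for j in range(n_batch)])

    gamma_star = np.zeros_like(gamma_hat)
    delta_star = np.zeros_like(delta_hat)
    n_iter = {}
    for j, b in enumerate(batches):
        Zb = Z[:, batch_masks[b]]
        g_old = gamma_hat[:, j].copy()
        d_old = delta_hat[:, j].copy()
        n = n_obs_gb[:, j]
        count = 0
        change = np.inf
        while change > conv and count < max_iter:
            g_new = (n * tau_sq[j] * gamma_hat[:, j] + d_old * gamma_bar[j]) / (
                n * tau_sq[j] + d_old
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sum2 = np.nansum((Zb - g_new[:, None]) ** 2, axis=1)
            d_new = (0.5 * sum2 + b_prior[j]) / (n / 2.0 + a_prior[j] - 1.0)
            change = max(
                np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
                np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
            )
            g_old, d_old = g_new, d_new
            count += 1
        gamma_star[:, j] = g_old
        delta_star[:, j] = d_old
        n_iter[str(b)] = count

    adjusted = Z.copy()
    for j, b in enumerate(batches):
        mask = batch_masks[b]
        adjusted[:, mask] = (Z[:, mask] - gamma_star[:, [j]]) / np.sqrt(delta_star[:, [j]])
    adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean

    wide_adj = pd.DataFrame(adjusted, index=wide.index, columns=wide.columns)
    out = joined.loc[:, ["feature_id", "sample_id"]].copy()
    flat = wide_adj.stack(future_stack=True)
    out["intensity"] = flat.loc[
        pd.MultiIndex.from_frame(out[["feature_id", "sample_id"]])
    ].to_numpy()

    params = CombatParams(
        batches=[str(b) for b in batches],
        stand_mean=pd.DataFrame(stand_mean, index=wide.index, columns=wide.columns),
        var_pooled=pd.Series(var_pooled, index=wide.index),
        gamma_hat=pd.DataFrame(gamma_hat, index=wide.index, columns=batches),
        delta_hat=pd.DataFrame(delta_hat, index=wide.index, columns=batches),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        tau_sq=pd.Series(tau_sq, index=batches),
        a_prior=pd.Series(a_prior, index=batches),
        b_prior=pd.Series(b_prior, index=batches),
        gamma_star=pd.DataFrame(gamma_star, index=wide.index, columns=batches),
        delta_star=pd.DataFrame(delta_star, index=wide.index, columns=batches),
        n_iter=n_iter,
        tol=conv,
    )
    return out, params


def adjust_two_step(
    table: pd.DataFrame,
    annotation: SampleAnnotation,
    batch_factor: str,
    span: float = 0.75,
    degree: int = 2,
    min_points: int = 8,
    discrete_method: str = "median",
    covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Two-step correction: LOESS drift removal, then discrete correction.

    ``discrete_method`` is 'median', 'mean' or 'combat'.  Returns the
    corrected table and a run log with the parameters and fallback counts of
    both steps.
    """
    drifted, fits = correct_drift(
        table, annotation, batch_factor, span=span, degree=degree, min_points=min_points
    )
    log = {
        "step1": {
            "method": "loess",
            "span": span,
            "degree": degree,
            "min_points": min_points,
            "n_fits": sum(not f.fallback for f in fits),
            "n_fallbacks": sum(f.fallback for f in fits),
        },
        "_fits": fits,  # stripped before serialization by callers
    }
    if discrete_method in ("median", "mean"):
        out = center_discrete(drifted, annotation, batch_factor, stat=discrete_method)
        log["step2"] = {"method": f"{discrete_method}_centering"}
    elif discrete_method == "combat":
        out, params = combat(drifted, annotation, batch_factor, covariates=covariates)
        log["step2"] = {"method": "combat", "n_iter": params.n_iter}
    else:
        raise ValueError(f"unknown discrete_method '{discrete_method}'")
    log["batch_factor"] = batch_factor
    return out, log
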