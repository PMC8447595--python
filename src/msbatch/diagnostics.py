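"""Diagnostics of batch structure: order summaries, PCA, clustering, PVCA.

These are the assessment tools of workflow steps 1 and 3: they quantify how
much of the variation in a (raw or normalized) peptide matrix is associated
with annotated technical factors, and whether continuous run-order trends
are present.

A recurring hazard: PCA, hierarchical clustering and PVCA need complete
matrices, and batch-coupled missing values that are zero-filled masquerade
as batch effects.  The default policy here is therefore to subset to
complete features and report how many were dropped; filling is available
only behind an explicit flag that warns.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
import statsmodels.api as sm

from .model import SampleAnnotation, validate_long, long_to_wide


def sample_order_summary(
    table: pd.DataFrame,
    annotation: SampleAnnotation,
    stat: str = "median",
) -> pd.DataFrame:
    """Per-sample intensity summaries in running order.

    One row per sample sorted by run_order with the chosen location
    statistic, quartiles and the count of observations outside the
    1.5 x IQR fences — the tabular backbone of drift plots and intensity
    boxplots.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    table = validate_long(table, annotation)
    rows = []
    groups = dict(tuple(table.groupby("sample_id")["intensity"]))
    ann = annotation.frame.sort_values("run_order")
    factor_cols = list(annotation.batch_factors) + list(annotation.bio_factors)
    for _, arow in ann.iterrows():
        sid = arow["sample_id"]
        vals = groups.get(sid, pd.Series(dtype=float)).to_numpy(dtype=float)
        if len(vals) == 0:
            rec = dict(sample_id=sid, run_order=arow["run_order"], n_observed=0,
                       value=np.nan, q1=np.nan, q3=np.nan, n_outliers=0)
        else:
            q1, q3 = np.quantile(vals, [0.25, 0.75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            rec = dict(
                sample_id=sid,
                run_order=int(arow["run_order"]),
                n_observed=len(vals),
                value=float(np.median(vals) if stat == "median" else np.mean(vals)),
                q1=float(q1),
                q3=float(q3),
                n_outliers=int(((vals < lo) | (vals > hi)).sum()),
            )
        for c in factor_cols:
            rec[c] = arow[c]
        rows.append(rec)
    return pd.DataFrame(rows)


def _complete_matrix(
    table: pd.DataFrame,
    annotation: SampleAnnotation | None = None,
    missing_policy: str = "complete_features",
    fill_value: float = 0.0,
) -> tuple[pd.DataFrame, int]:
    """Features x samples matrix under a missing-value policy.

    Returns the matrix and the number of incomplete features dropped (or 0
    when filling).  ``missing_policy``: 'complete_features' (default),
    'error', or 'fill' (explicit, warned — see Box-type hazards).
    """
    wide = long_to_wide(table)
    if annotation is not None:
        # all annotated samples define the column universe
        wide = wide.reindex(columns=annotation.sample_ids)
    complete = wide.dropna(axis=0)
    n_dropped = len(wide) - len(complete)
    if missing_policy == "complete_features":
        return complete, n_dropped
    if missing_policy == "error":
        if n_dropped:
            raise ValueError(
                f"{n_dropped} features have missing values; filter or choose a policy"
            )
        return complete, 0
    if missing_policy == "fill":
        warnings.warn(
            f"filling missing cells of {n_dropped} incomplete features with "
            f"{fill_value}; batch-coupled missingness will inflate apparent "
            "batch effects in PCA/clustering/PVCA",
            UserWarning,
            stacklevel=3,
        )
        return wide.fillna(fill_value), 0
    raise ValueError(f"unknown missing_policy '{missing_policy}'")


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray  # fraction of total variance per component
    features_used: list
    n_features_dropped: int


def pca_scores(
    table: pd.DataFrame,
    annotation: SampleAnnotation | None = None,
    n_components: int | None = None,
    missing_policy: str = "complete_features",
    scale: bool = False,
) -> PcaResult:
    """Principal component scores of samples from feature-centred data.

    Features are centred (optionally unit-scaled) across samples; scores are
    computed by SVD of the samples x features matrix.  Variance fractions
    are relative to the total variance, as printed in PC axis labels.
    """
    mat, n_dropped = _complete_matrix(table, annotation, missing_policy)
    if mat.shape[0] < 2:
        raise ValueError(
            "fewer than 2 complete features; run completeness_filter or choose "
            "an explicit imputation policy first"
        )
    if mat.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = mat.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| coordinate positive
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    total = (s**2).sum()
    var_frac = s**2 / total if total > 0 else np.zeros_like(s)
    k = len(s) if n_components is None else min(n_components, len(s))
    scores = pd.DataFrame(
        (U[:, :k] * s[:k]),
        index=mat.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(scores, var_frac[:k], list(mat.index), n_dropped)


@dataclass
class DendrogramReport:
    merges: np.ndarray  # scipy linkage matrix, (n-1) x 4
    heights: np.ndarray
    distance: str
    linkage: str
    leaf_order: list
    labels: pd.DataFrame  # per-leaf factor labels
    n_features_dropped: int


_DISTANCES = {"euclidean": "euclidean", "manhattan": "cityblock", "correlation": "correlation"}


def hierarchical_cluster(
    table: pd.DataFrame,
    annotation: SampleAnnotation | None = None,
    distance: str = "euclidean",
    linkage: str = "complete",
    missing_policy: str = "complete_features",
) -> DendrogramReport:
    """Agglomerative clustering of samples with factor labels per leaf.

    Distance: euclidean, manhattan, or correlation (1 - Pearson r);
    linkage: complete, average, or ward (euclidean only).
    """
    if distance not in _DISTANCES:
        raise ValueError(f"unknown distance '{distance}'")
    if linkage not in ("complete", "average", "ward"):
        raise ValueError(f"unknown linkage '{linkage}'")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    mat, n_dropped = _complete_matrix(table, annotation, missing_policy)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 complete features and 2 samples")
    X = mat.to_numpy(dtype=float).T
    D = ssd.pdist(X, metric=_DISTANCES[distance])
    Z = sch.linkage(D, method=linkage)
    leaves = [mat.columns[i] for i in sch.leaves_list(Z)]
    if annotation is not None:
        labels = annotation.frame.set_index("sample_id").loc[list(mat.columns)]
        labels = labels[
            ["run_order"] + list(annotation.batch_factors) + list(annotation.bio_factors)
        ].reset_index()
    else:
        labels = pd.DataFrame({"sample_id": list(mat.columns)})
    return DendrogramReport(
        merges=Z,
        heights=Z[:, 2].copy(),
        distance=distance,
        linkage=linkage,
        leaf_order=leaves,
        labels=labels,
        n_features_dropped=n_dropped,
    )


@dataclass
class PvcaResult:
    """Eigenvalue-weighted variance-component attribution per factor."""

    proportions: pd.Series  # source -> weighted proportion (sums to 1)
    n_components: int
    variance_threshold: float
    eigenvalue_fractions: np.ndarray  # per retained component
    n_features_dropped: int

    def __getitem__(self, source: str) -> float:
        return float(self.proportions[source])


def _direct_reml(y: np.ndarray, level_codes: dict) -> dict:
    """Direct REML for a crossed random-intercept model, Nelder-Mead on the
    log-variances.  Fallback for boundary cases where the standard
    mixed-model fit fails (singular Hessian at a zero component).

    Returns {source: variance} including 'residual'.
    """
    n = len(y)
    names = list(level_codes)
    ZZt = []
    for codes in level_codes.values():
        Z = np.zeros((n, int(codes.max()) + 1))
        Z[np.arange(n), codes] = 1.0
        ZZt.append(Z @ Z.T)
    X = np.ones((n, 1))

    def neg_reml(log_var):
        vs = np.exp(np.clip(log_var, -30, 30))
        V = vs[-1] * np.eye(n)
        for v, M in zip(vs[:-1], ZZt):
            V = V + v * M
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            return 1e10
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        return float(
            0.5 * (logdet + np.linalg.slogdet(XtViX)[1] + r @ Vi @ r)
        )

    from scipy.optimize import minimize

    start = np.log(np.full(len(names) + 1, max(y.var(ddof=1), 1e-6) / (len(names) + 1)))
    best = minimize(neg_reml, start, method="Nelder-Mead",
                    options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    vs = np.exp(best.x)
    out = {name: float(v) for name, v in zip(names, vs[:-1])}
    out["residual"] = float(vs[-1])
    return out


def _partitions_identical(a: pd.Series, b: pd.Series) -> bool:
    codes_a = pd.factorize(a)[0]
    codes_b = pd.factorize(b)[0]
    return bool(pd.crosstab(codes_a, codes_b).gt(0).sum().eq(1).all()
                and pd.crosstab(codes_b, codes_a).gt(0).sum().eq(1).all())


def pvca(
    table: pd.DataFrame,
    annotation: SampleAnnotation,
    factors: list[str],
    include_pairwise_interactions: bool = False,
    variance_threshold: float = 0.6,
    missing_policy: str = "complete_features",
) -> PvcaResult:
    """Principal variance component analysis.

    Retains the smallest set of leading PCs reaching the cumulative variance
    threshold; per PC, fits a random-intercept model (REML) with one
    variance component per factor (and per pairwise interaction when
    requested); normalizes the components plus residual within each PC,
    weights by the PC's eigenvalue fraction among the retained set, and
    renormalizes to 1.
    """
    for f in factors:
        if f not in annotation.frame.columns:
            raise KeyError(f"unknown factor '{f}'")
        if annotation.frame[f].nunique() < 2:
            raise ValueError(f"factor '{f}' has fewer than 2 levels")
    for fa, fb in itertools.combinations(factors, 2):
        if _partitions_identical(annotation.column(fa), annotation.column(fb)):
            raise ValueError(
                f"factors '{fa}' and '{fb}' induce identical sample partitions "
                "and cannot be separated"
            )

    pca = pca_scores(table, annotation, missing_policy=missing_policy)
    cum = np.cumsum(pca.variance_fraction)
    k = int(np.searchsorted(cum, variance_threshold) + 1)
    k = min(k, pca.scores.shape[1])
    ev = pca.variance_fraction[:k]
    ev_weights = ev / ev.sum()

    data = annotation.frame.set_index("sample_id").loc[list(pca.scores.index)].copy()
    terms = {f: f for f in factors}
    if include_pairwise_interactions:
        for fa, fb in itertools.combinations(factors, 2):
            name = f"{fa}:{fb}"
            data[name.replace(":", "__x__")] = (
                data[fa].astype(str) + "/" + data[fb].astype(str)
            )
            terms[name] = name.replace(":", "__x__")

    sources = list(terms.keys()) + ["residual"]
    combined = pd.Series(0.0, index=sources)
    n = len(data)
    for i in range(k):
        df = data.copy()
        df["score"] = pca.scores.iloc[:, i].to_numpy()
        df["_g"] = 1
        # unit-variance response improves optimizer conditioning;
        # proportions are scale-invariant
        sd = df["score"].std(ddof=1)
        if sd > 0:
            df["score"] = df["score"] / sd
        vcf = {name: f"0 + C({col})" for name, col in terms.items()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM.from_formula(
                "score ~ 1", groups="_g", vc_formula=vcf, re_formula="0", data=df
            )
            # gradient methods can stop at inferior local optima (and still
            # report convergence); fit with several optimizers and keep the
            # best restricted likelihood reached
            attempts = []
            for method in ("lbfgs", "powell", "nm"):
                try:
                    attempts.append(md.fit(reml=True, method=method, maxiter=2000))
                except (np.linalg.LinAlgError, ValueError):
                    continue
        comps = pd.Series(0.0, index=sources)
        if attempts:
            res = max(attempts, key=lambda r: r.llf)
            for name, est in zip(md.exog_vc.names, res.vcomp):
                comps[name] = max(float(est), 0.0)
            comps["residual"] = max(float(res.scale), 0.0)
        else:
            # every optimizer died (typically a singular Hessian at a zero
            # component); fall back to a direct REML optimization
            codes = {
                name: pd.factorize(df[col])[0] for name, col in terms.items()
            }
            direct = _direct_reml(df["score"].to_numpy(dtype=float), codes)
            for name, est in direct.items():
                comps[name] = max(est, 0.0)
        comps = comps / comps.sum()
        combined += ev_weights[i] * comps
    combined = combined / combined.sum()
    return PvcaResult(
        proportions=combined,
        n_components=k,
        variance_threshold=variance_threshold,
        eigenvalue_fractions=ev,
        n_features_dropped=pca.n_features_dropped,
    )


def feature_trend(
    table: pd.DataFrame,
    annotation: SampleAnnotation,
    feature_ids: list,
) -> pd.DataFrame:
    """Long table of selected features in running order, for drift plots.

    Spike-in features (constant true amount) are the canonical choice: their
    apparent variation is purely technical.
    """
    table = validate_long(table, annotation)
    unknown = set(feature_ids) - set(table["feature_id"])
    if unknown:
        raise KeyError(f"unknown feature ids: {sorted(unknown)}")
    sub = table.loc[table["feature_id"].isin(set(feature_ids))].copy()
    sub["run_order"] = sub["sample_id"].map(annotation.column("run_order"))
    for f in annotation.batch_factors:
        sub[f] = sub["sample_id"].map(annotation.column(f))
    return sub.sort_values(["feature_id", "run_order"]).reset_index(drop=True)


def confounding_report(
    annotation: SampleAnnotation, factor_x: str, factor_y: str
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulation of two factors plus Cramér's V in [0, 1].

    V = 1 means the factors are fully confounded (identical partitions up to
    relabeling) and cannot be separated by any correction.
    """
    for f in (factor_x, factor_y):
        if f not in annotation.frame.columns:
            raise KeyError(f"unknown factor '{f}'")
    tab = pd.crosstab(annotation.frame[factor_x], annotation.frame[factor_y])
    n = tab.to_numpy().sum()
    r, c = tab.shape
    if min(r, c) < 2:
        return tab, 0.0
    chi2 = scipy.stats.chi2_contingency(tab, correction=False).statistic
    v = float(np.sqrt(chi2 / (n * (min(r, c) - 1))))
    return tab, min(v, 1.0)
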