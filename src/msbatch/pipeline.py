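"""Config-driven execution of the five-step workflow.

A YAML config names the inputs, the factor roles, and — explicitly — the
method and parameters of every step to run.  There is deliberately no
default method anywhere: the choice of normalization and correction must
reflect the properties of the dataset, so a step missing from the config is
simply skipped.  Every run writes per-step TSV outputs plus a
machine-readable JSON run log (methods, parameters, seed, dropped-feature
counts, warnings).

Steps, in fixed order: ``assess`` -> ``normalize`` -> ``diagnose`` ->
``correct`` -> ``qc``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import yaml

from . import io as msio
from .correct import adjust_two_step, center_discrete, combat, drift_fits_frame
from .diagnostics import (
    confounding_report,
    hierarchical_cluster,
    pca_scores,
    pvca,
    sample_order_summary,
)
from .normalize import normalize
from .qc import qc_compare

STEP_ORDER = ("assess", "normalize", "diagnose", "correct", "qc")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_workflow(config: dict | str | Path, out_dir=None) -> dict:
    """Execute the steps named in *config*; return the run log.

    The log records, per executed step, the method, its parameters and any
    warnings raised; it is also written to ``run_log.json`` in the artifact
    directory.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir or config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    inp = config["input"]
    table = msio.read_long(inp["long"])
    annotation = msio.read_sample_annotation(
        inp["sample_annotation"], roles=inp.get("factor_roles")
    )
    features = (
        msio.read_feature_annotation(inp["feature_annotation"])
        if inp.get("feature_annotation")
        else None
    )
    steps = config.get("steps", {})
    unknown = set(steps) - set(STEP_ORDER)
    if unknown:
        raise ValueError(f"unknown steps in config: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    log: dict = {"seed": seed, "steps": {}, "warnings": []}

    raw = table
    current = table
    corrected = None

    def _run(step, fn):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"step '{step}' failed: {exc}") from exc
        for w in caught:
            log["warnings"].append({"step": step, "message": str(w.message)})
        return result

    if "assess" in steps:
        params = steps["assess"] or {}
        stat = params.get("stat", "median")
        summary = _run("assess", lambda: sample_order_summary(current, annotation, stat=stat))
        summary.to_csv(out_dir / "assess_sample_order.tsv", sep="\t", index=False)
        log["steps"]["assess"] = {"stat": stat}

    if "normalize" in steps:
        params = steps["normalize"] or {}
        if "method" not in params:
            raise ValueError("the normalize step must name a method explicitly")
        method = params["method"]
        current = _run("normalize", lambda: normalize(current, method))
        msio.write_long(current, out_dir / "normalized.tsv")
        log["steps"]["normalize"] = {"method": method}

    if "diagnose" in steps:
        params = steps["diagnose"] or {}
        entry: dict = {}
        if params.get("pca", True):
            res = _run("diagnose", lambda: pca_scores(current, annotation))
            res.scores.to_csv(out_dir / "diagnose_pca_scores.tsv", sep="\t")
            entry["pca"] = {
                "variance_fraction": [float(v) for v in res.variance_fraction[:10]],
                "n_features_dropped": res.n_features_dropped,
            }
        if params.get("hclust"):
            hp = params["hclust"] if isinstance(params["hclust"], dict) else {}
            rep = _run(
                "diagnose",
                lambda: hierarchical_cluster(
                    current,
                    annotation,
                    distance=hp.get("distance", "euclidean"),
                    linkage=hp.get("linkage", "complete"),
                ),
            )
            rep.labels.assign(leaf_rank=[rep.leaf_order.index(s) for s in rep.labels["sample_id"]]).to_csv(
                out_dir / "diagnose_hclust_leaves.tsv", sep="\t", index=False
            )
            entry["hclust"] = {"distance": rep.distance, "linkage": rep.linkage}
        if params.get("pvca_factors"):
            res = _run(
                "diagnose",
                lambda: pvca(
                    current,
                    annotation,
                    list(params["pvca_factors"]),
                    include_pairwise_interactions=params.get("pvca_interactions", False),
                ),
            )
            res.proportions.rename("weighted_proportion").to_csv(
                out_dir / "diagnose_pvca.tsv", sep="\t"
            )
            entry["pvca"] = {
                "proportions": {k: float(v) for k, v in res.proportions.items()},
                "n_components": res.n_components,
            }
        if params.get("confounding"):
            fx, fy = params["confounding"]
            tab, v = _run("diagnose", lambda: confounding_report(annotation, fx, fy))
            tab.to_csv(out_dir / "diagnose_confounding.tsv", sep="\t")
            entry["confounding"] = {
                "factors": [fx, fy],
                "cramers_v": v,
                "fully_confounded": bool(v >= 1.0 - 1e-12),
            }
        log["steps"]["diagnose"] = entry

    if "correct" in steps:
        params = steps["correct"] or {}
        if "method" not in params or "batch_factor" not in params:
            raise ValueError("the correct step must name method and batch_factor explicitly")
        method = params["method"]
        bf = params["batch_factor"]
        if method in ("loess+median", "loess+mean", "loess+combat"):
            discrete = method.split("+")[1]
            corrected, steplog = _run(
                "correct",
                lambda: adjust_two_step(
                    current,
                    annotation,
                    bf,
                    span=float(params.get("span", 0.75)),
                    degree=int(params.get("degree", 2)),
                    min_points=int(params.get("min_points", 8)),
                    discrete_method=discrete,
                    covariates=params.get("covariates"),
                ),
            )
            fits = steplog.pop("_fits", [])
            if params.get("fits_out", True):
                drift_fits_frame(fits).to_csv(
                    out_dir / "drift_fits.tsv", sep="\t", index=False
                )
        elif method in ("median", "mean"):
            corrected = _run(
                "correct", lambda: center_discrete(current, annotation, bf, stat=method)
            )
            steplog = {"step2": {"method": f"{method}_centering"}, "batch_factor": bf}
        elif method == "combat":
            corrected, cparams = _run(
                "correct",
                lambda: combat(current, annotation, bf, covariates=params.get("covariates")),
            )
            steplog = {
                "step2": {"method": "combat", "n_iter": cparams.n_iter},
                "batch_factor": bf,
            }
        else:
            raise ValueError(f"unknown correction method '{method}'")
        msio.write_long(corrected, out_dir / "corrected.tsv")
        log["steps"]["correct"] = {"method": method, **steplog}

    if "qc" in steps:
        params = steps["qc"] or {}
        bf = params.get("batch_factor") or (steps.get("correct") or {}).get("batch_factor")
        if bf is None:
            raise ValueError("the qc step needs a batch_factor")
        if features is None:
            raise ValueError("the qc step needs a feature annotation")
        after = corrected if corrected is not None else current
        report = _run(
            "qc",
            lambda: qc_compare(
                raw,
                after,
                annotation,
                features,
                bf,
                min_overlap=int(params.get("min_overlap", 50)),
                seed=seed,
            ),
        )
        qc_log = {
            stage: {
                k: float(v)
                for k, v in report[stage].items()
                if isinstance(v, (int, float))
            }
            for stage in ("before", "after", "delta")
        }
        with open(out_dir / "qc_report.json", "w") as fh:
            json.dump(qc_log, fh, indent=2)
        for stage in ("before", "after"):
            report[stage]["sample_correlation"].summary().to_csv(
                out_dir / f"qc_sample_correlation_{stage}.tsv", sep="\t", index=False
            )
        log["steps"]["qc"] = qc_log

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return log
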