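"""End-to-end study pipeline: cohort -> univariable tables -> screened
stepwise logistic regression -> ELM ensemble -> ROC comparison.

One master seed drives every random stage (cohort draw, per-classifier
under-samples and hidden layers, bootstrap CIs) through independent
spawned substreams, so a run is exactly reproducible and every emitted
number is recomputable from the emitted cohort CSV and the seed.

By default both models are trained and evaluated on the same cohort
(apparent performance, as in the source analysis), and the logistic model
entering the comparison is refit with the four published predictors
(road traffic accident, loss of consciousness, vomiting, base-of-skull
fracture signs) rather than whatever stepwise returns on a particular
synthetic draw; ``data_driven_logit=True`` switches to screen+stepwise
selection, and ``cv`` enables stratified k-fold scoring as an extension.
"""

from __future__ import annotations

import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, elm_ensemble, evaluation, logit_model
from .synthetic_data import (
    CASE,
    CONTROL,
    LOGISTIC_PREDICTORS,
    MODEL_PREDICTORS,
    Cohort,
    CohortSpec,
    fixture_cohort,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)

__all__ = ["RunConfig", "run_study", "compare_models"]

log = logging.getLogger("tbipred")


@dataclass
class RunConfig:
    """Configuration of a full study run."""

    cohort_source: str = "synthetic"  # "synthetic" | "fixture" | CSV path
    n_cases: int = 39
    control_ratio: int = 4
    rho: float = 0.0
    logit_variables: tuple[str, ...] = LOGISTIC_PREDICTORS
    ml_variables: tuple[str, ...] = MODEL_PREDICTORS
    ensemble_size: int = 100
    n_hidden: int = 30
    data_driven_logit: bool = False
    n_boot: int = 2000
    cv: int = 0  # 0 = apparent performance; k >= 2 = stratified k-fold
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("logit_variables", "ml_variables"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_cohort(config: RunConfig, rng_seed: int) -> Cohort:
    if config.cohort_source == "synthetic":
        spec = CohortSpec(n_cases=config.n_cases,
                          control_ratio=config.control_ratio,
                          rho=config.rho, seed=rng_seed)
        return generate_cohort(spec)
    if config.cohort_source == "fixture":
        return fixture_cohort(seed=rng_seed)
    return read_cohort_csv(config.cohort_source)


def _cv_scores(cohort: Cohort, config: RunConfig, seeds) -> tuple[np.ndarray, np.ndarray]:
    """Stratified k-fold out-of-fold scores for both models."""
    from sklearn.model_selection import StratifiedKFold

    y = cohort.data["group"].to_numpy(dtype=int)
    Xlr = cohort.data[list(config.logit_variables)]
    Xml = elm_ensemble.features_matrix(cohort, list(config.ml_variables))
    lr_scores = np.full(len(y), np.nan)
    ml_scores = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=config.cv, shuffle=True, random_state=seeds[0])
    for k, (tr, te) in enumerate(skf.split(Xml, y)):
        fit = logit_model.fit_logistic(Xlr.iloc[tr], y[tr],
                                       names=list(config.logit_variables))
        sub = Cohort(cohort.data.iloc[te], provenance="cv")
        lr_scores[te] = logit_model.predict_prob_cohort(fit, sub)
        ens = elm_ensemble.build_ensemble(
            Xml[tr][y[tr] == CASE], Xml[tr][y[tr] == CONTROL],
            T=config.ensemble_size, n_hidden=config.n_hidden,
            seed=seeds[1] + k, feature_names=list(config.ml_variables))
        ml_scores[te] = elm_ensemble.score_cohort(ens, Xml[te])
    return lr_scores, ml_scores


def run_study(config: RunConfig) -> dict:
    """Execute the full analysis and return the artifact bundle.

    The bundle holds the cohort, univariable report, both fitted models,
    scores, performance reports and the model comparison. When
    ``config.outdir`` is set, all tables are also written there (CSV/JSON)
    atomically: outputs land only if every stage succeeded.
    """
    # deterministic substream seeds derived from the master seed
    ss = np.random.SeedSequence(config.seed)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(5)]
    cohort_seed, ens_seed, boot_lr_seed, boot_ml_seed, cv_seed = sub

    stage = "load_cohort"
    try:
        cohort = _load_cohort(config, cohort_seed)

        stage = "univariable"
        report = cohort_stats.univariable_report(cohort)

        stage = "logistic_selection"
        screened = logit_model.univariable_screen(cohort)
        y = cohort.data["group"].to_numpy(dtype=int)
        # subgroup items (structurally missing outside their age band)
        # cannot enter a model fitted on the full cohort
        multivariable = [v for v in screened if cohort.data[v].notna().all()]
        stepwise = None
        if multivariable:
            stepwise = logit_model.stepwise_select(cohort.data[multivariable], y)

        stage = "logistic_fit"
        if config.data_driven_logit and stepwise is not None and stepwise.names:
            lr_fit = stepwise
        else:
            lr_fit = logit_model.fit_logistic(
                cohort.data[list(config.logit_variables)], y,
                names=list(config.logit_variables))
        or_table = logit_model.odds_ratios(lr_fit)

        stage = "ensemble"
        Xml = elm_ensemble.features_matrix(cohort, list(config.ml_variables))
        ens = elm_ensemble.build_ensemble(
            Xml[y == CASE], Xml[y == CONTROL], T=config.ensemble_size,
            n_hidden=config.n_hidden, seed=ens_seed,
            feature_names=list(config.ml_variables))

        stage = "scoring"
        if config.cv and config.cv >= 2:
            lr_scores, ml_scores = _cv_scores(cohort, config, (cv_seed, ens_seed))
        else:
            lr_scores = logit_model.predict_prob_cohort(lr_fit, cohort)
            ml_scores = elm_ensemble.score_cohort(ens, cohort)

        stage = "evaluation"
        lr_curve = evaluation.roc_curve(lr_scores, y)
        ml_curve = evaluation.roc_curve(ml_scores, y)
        lr_cut = evaluation.optimal_cutoff(lr_curve)
        ml_cut = evaluation.optimal_cutoff(ml_curve)
        lr_perf = evaluation.confusion_metrics(lr_scores, y, lr_cut,
                                               n_boot=config.n_boot, seed=boot_lr_seed)
        ml_perf = evaluation.confusion_metrics(ml_scores, y, ml_cut,
                                               n_boot=config.n_boot, seed=boot_ml_seed)
        lr_hist = evaluation.score_histogram(lr_scores, y, bin_width=0.1, hi=1.0)
        ml_hist = evaluation.score_histogram(ml_scores, y, bin_width=10.0, hi=100.0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle = {
        "config": asdict(config),
        "cohort": cohort,
        "univariable": report,
        "screened": screened,
        "stepwise": stepwise,
        "lr_fit": lr_fit,
        "odds_ratios": or_table,
        "ensemble": ens,
        "lr_scores": lr_scores,
        "ml_scores": ml_scores,
        "lr_curve": lr_curve,
        "ml_curve": ml_curve,
        "lr_perf": lr_perf,
        "ml_perf": ml_perf,
        "lr_hist": lr_hist,
        "ml_hist": ml_hist,
    }
    bundle["comparison"] = compare_models(bundle, seed=boot_ml_seed)

    if config.outdir is not None:
        _write_bundle(bundle, config)
    return bundle


def compare_models(bundle: dict, n_boot: int = 2000,
                   seed: int | np.random.Generator = 0) -> dict:
    """Side-by-side metrics and the AUC difference (ML minus logistic)
    with a paired-bootstrap percentile CI."""
    from sklearn.metrics import roc_auc_score

    y = bundle["cohort"].data["group"].to_numpy(dtype=int)
    lr, ml = np.asarray(bundle["lr_scores"]), np.asarray(bundle["ml_scores"])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diffs = []
    n = len(y)
    while len(diffs) < n_boot:
        idx = rng.integers(0, n, size=n)
        if y[idx].min() == y[idx].max():
            continue
        diffs.append(roc_auc_score(y[idx], ml[idx]) - roc_auc_score(y[idx], lr[idx]))
    lo, hi = np.quantile(diffs, [0.025, 0.975])
    lrp, mlp = bundle["lr_perf"], bundle["ml_perf"]
    side_by_side = {
        m: {"ml": getattr(mlp, m), "logistic": getattr(lrp, m)}
        for m in ("auc", "sensitivity", "specificity", "ppv", "npv", "cutoff")
    }
    return {
        "metrics": side_by_side,
        "auc_difference": float(mlp.auc - lrp.auc),
        "auc_difference_ci": [float(lo), float(hi)],
    }


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    """Write every artifact; stage into a temp dir then move, so a failed
    run leaves no partial outputs."""
    outdir = Path(config.outdir)
    tmp = Path(tempfile.mkdtemp(prefix="tbipred_"))
    try:
        write_cohort_csv(bundle["cohort"], tmp / "cohort.csv")
        cohort_stats.report_to_csv(bundle["univariable"], tmp / "univariable.csv")
        cohort_stats.report_to_json(bundle["univariable"], tmp / "univariable.json")
        logit_model.model_to_json(bundle["lr_fit"], tmp / "logit_fit.json")
        pd.DataFrame([asdict(r) for r in bundle["odds_ratios"]]).to_csv(
            tmp / "odds_ratios.csv", index=False)
        if bundle["stepwise"] is not None:
            logit_model.model_to_json(bundle["stepwise"], tmp / "stepwise_fit.json")
        elm_ensemble.ensemble_to_json(bundle["ensemble"], tmp / "ensemble.json")
        for tag in ("lr", "ml"):
            curve = bundle[f"{tag}_curve"]
            pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr,
                          "threshold": curve.thresholds}).to_csv(
                tmp / f"roc_{tag}.csv", index=False)
            evaluation.report_to_json(bundle[f"{tag}_perf"], tmp / f"perf_{tag}.json")
            bundle[f"{tag}_hist"].to_csv(tmp / f"hist_{tag}.csv")
        with open(tmp / "comparison.json", "w") as fh:
            json.dump(bundle["comparison"], fh, indent=2)
        with open(tmp / "run_log.json", "w") as fh:
            json.dump({"config": asdict(config),
                       "versions": _versions()}, fh, indent=2)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    outdir.mkdir(parents=True, exist_ok=True)
    for f in tmp.iterdir():
        shutil.move(str(f), outdir / f.name)
    tmp.rmdir()
    log.info("run artifacts written to %s", outdir)


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "statsmodels": statsmodels.__version__,
            "sklearn": sklearn.__version__}
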