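"""End-to-end pipeline: simulate -> annotate -> stats -> scatter ->
clinical -> select -> classify.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so any stage can be re-run in isolation from the persisted
intermediates.  A JSON manifest records the configuration echo, library
versions, per-stage status, and SHA-256 hashes of the data artifacts
(plots are excluded from hashing); re-running with the same configuration
reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_records, metrics_table
from .classify import ModelSpec, benchmark, export_roc, integrate_features
from .clinical import lasso_select, prepare_clinical
from .errors import ConfigurationError, DataError
from .io import read_records, write_records
from .records import SUBTYPE_DEFAULTS
from .scattering import build_network, feature_matrix, plot_filter_banks
from .stats import (compare_all_metrics, comparisons_frame, export_boxplots,
                    export_qq_plots, select_time_features)
from .synth import CLINICAL_SCHEMA, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "annotate", "stats", "scatter", "clinical", "select",
          "classify")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "aepkit-run",
    "cohort": {},              # CohortConfig overrides
    "scattering": {
        "abr": {"invariance_scale_s": 0.006, "q_factors": [8, 1],
                "signal_length": 450},
        "amlr": {"invariance_scale_s": 0.081, "q_factors": [8, 1],
                 "signal_length": 420},
    },
    "stats": {"alpha": 0.05},
    "lasso": {"folds": 10, "repeats": 100, "selection_threshold": 0.5},
    "models": list(("lda", "svm_linear", "svm_radial", "svm_poly",
                    "naive_bayes", "neural_net", "random_forest")),
    "folds": 10,
    "plots": True,
}


def merge_config(user: dict | None) -> dict:
    """DEFAULT_CONFIG overlaid with a (possibly nested) user dict."""
    def merge(base, over):
        out = dict(base)
        for k, v in (over or {}).items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                out[k] = merge(base[k], v)
            else:
                out[k] = v
        return out
    cfg = merge(DEFAULT_CONFIG, user)
    if "seed" not in cfg or cfg["seed"] is None:
        raise ConfigurationError("run config requires a seed")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _outdir(config: dict) -> Path:
    out = Path(config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


# ------------------------------------------------------------------ stages

def stage_simulate(config: dict) -> list[Path]:
    out = _outdir(config)
    cc = CohortConfig(seed=config["seed"], **config["cohort"])
    cohort = generate_cohort(cc)
    write_records(cohort.records_of("ABR"), out / "abr_records.xml")
    write_records(cohort.records_of("AMLR"), out / "amlr_records.xml")
    cohort.clinical.to_csv(out / "clinical_raw.csv")
    cohort.labels.to_csv(out / "labels.csv")
    return [out / "abr_records.xml", out / "amlr_records.xml",
            out / "clinical_raw.csv", out / "labels.csv"]


def stage_annotate(config: dict) -> list[Path]:
    out = _outdir(config)
    anns = []
    for name in ("abr", "amlr"):
        anns.extend(annotate_records(read_records(out / f"{name}_records.xml")))
    table = metrics_table(anns)
    table.to_csv(out / "wave_metrics.csv", index=False)
    return [out / "wave_metrics.csv"]


def _load_labels(out: Path) -> pd.Series:
    return pd.read_csv(out / "labels.csv", index_col=0)["distress_group"]


def stage_stats(config: dict) -> list[Path]:
    out = _outdir(config)
    metrics = pd.read_csv(out / "wave_metrics.csv")
    labels = _load_labels(out)
    comparisons = compare_all_metrics(metrics, labels)
    frame = comparisons_frame(comparisons)
    frame.to_csv(out / "group_comparisons.csv", index=False)
    selected = select_time_features(comparisons, alpha=config["stats"]["alpha"])
    (out / "time_features.json").write_text(json.dumps(selected, indent=1))
    artifacts = [out / "group_comparisons.csv", out / "time_features.json"]
    if config.get("plots", True):
        export_qq_plots(metrics, labels, out / "plots" / "qq")
        export_boxplots(metrics, labels, out / "plots" / "box")
    return artifacts


def stage_scatter(config: dict) -> list[Path]:
    out = _outdir(config)
    artifacts = []
    for name in ("abr", "amlr"):
        sub = config["scattering"][name]
        records = read_records(out / f"{name}_records.xml")
        n = sub["signal_length"]
        fs = SUBTYPE_DEFAULTS[name.upper()]["fs_hz"]
        net = build_network(fs, n, sub["invariance_scale_s"],
                            tuple(sub["q_factors"]))
        signals, ids = [], []
        for rec in records:
            if rec.n_samples != n:
                rec = rec.truncated(n)
            signals.append(rec.samples)
            ids.append(rec.record_id)
        mat = feature_matrix(signals, net)
        from .scattering import scatter as _scatter
        labels = _scatter(signals[0], net).path_labels()
        frame = pd.DataFrame(mat, index=pd.Index(ids, name="record_id"),
                             columns=labels)
        path = out / f"wst_{name}.csv"
        frame.to_csv(path)
        artifacts.append(path)
        if config.get("plots", True):
            (out / "plots").mkdir(exist_ok=True)
            plot_filter_banks(net, out / "plots" / f"filterbank_{name}.png")
    return artifacts


def stage_clinical(config: dict) -> list[Path]:
    out = _outdir(config)
    raw = pd.read_csv(out / "clinical_raw.csv", index_col=0)
    features, labels = prepare_clinical(raw)
    features.to_csv(out / "clinical_features.csv")
    schema = {col: ("categorical" if CLINICAL_SCHEMA.get(col, ("numeric",))[0]
                    == "categorical" else "numeric")
              for col in features.columns}
    (out / "clinical_features.schema.json").write_text(
        json.dumps(schema, indent=1))
    labels.to_csv(out / "clinical_labels.csv")
    return [out / "clinical_features.csv",
            out / "clinical_features.schema.json", out / "clinical_labels.csv"]


def stage_select(config: dict) -> list[Path]:
    out = _outdir(config)
    features = pd.read_csv(out / "clinical_features.csv", index_col=0)
    labels = pd.read_csv(out / "clinical_labels.csv", index_col=0)[
        "distress_group"]
    sel = lasso_select(features, labels, seed=config["seed"],
                       **config["lasso"])
    sel.report().to_csv(out / "lasso_report.csv")
    (out / "clinical_selected.json").write_text(
        json.dumps(sel.selected, indent=1))
    return [out / "lasso_report.csv", out / "clinical_selected.json"]


def _ear_table(metrics: pd.DataFrame, selected: list) -> pd.DataFrame:
    """Record x selected-metric matrix from the long metric table."""
    metrics = metrics.copy()
    metrics["key"] = list(zip(metrics["subtype"], metrics["wave"],
                              metrics["metric"]))
    keys = [tuple(s) for s in selected]
    wide = metrics.pivot_table(index="record_id", columns="key",
                               values="value", aggfunc="first")
    cols = [k for k in keys if k in wide.columns]
    wide = wide[cols]
    # unfound waves: column-mean fill, so classifiers see finite inputs
    return wide.fillna(wide.mean())


def stage_classify(config: dict) -> dict:
    out = _outdir(config)
    labels = _load_labels(out)
    metrics = pd.read_csv(out / "wave_metrics.csv")
    selected_time = json.loads((out / "time_features.json").read_text())
    clin_features = pd.read_csv(out / "clinical_features.csv", index_col=0)
    clin_labels = pd.read_csv(out / "clinical_labels.csv", index_col=0)[
        "distress_group"]
    clin_selected = json.loads((out / "clinical_selected.json").read_text())
    wst_abr = pd.read_csv(out / "wst_abr.csv", index_col=0)
    wst_amlr = pd.read_csv(out / "wst_amlr.csv", index_col=0)

    patient_of = pd.Series({rid: metrics.loc[metrics["record_id"] == rid,
                                             "patient_id"].iloc[0]
                            for rid in metrics["record_id"].unique()})

    def ear_bundle(frame):
        pats = patient_of.loc[frame.index]
        return frame, labels.loc[pats].set_axis(frame.index), pats.to_numpy()

    # align ABR and AMLR ears: strip the subtype suffix from record ids
    abr_key = wst_abr.index.str.replace("-abr", "", regex=False)
    amlr_key = wst_amlr.index.str.replace("-amlr", "", regex=False)
    both = pd.concat([wst_abr.set_axis(abr_key).add_prefix("abr:"),
                      wst_amlr.set_axis(amlr_key).add_prefix("amlr:")],
                     axis=1, join="inner")
    ear_patient = pd.Series(both.index.str.rsplit("-", n=1).str[0],
                            index=both.index)

    feature_sets: dict[str, tuple] = {}
    if selected_time:
        tf = _ear_table(metrics, selected_time)
        tf.columns = ["/".join(c) for c in tf.columns]
        feature_sets["time_domain"] = ear_bundle(tf)
    feature_sets["wst_abr"] = ear_bundle(wst_abr)
    feature_sets["wst_amlr"] = ear_bundle(wst_amlr)
    feature_sets["wst_both"] = (both,
                                labels.loc[ear_patient].set_axis(both.index),
                                ear_patient.to_numpy())
    feature_sets["clinical_all"] = (clin_features, clin_labels)
    if clin_selected:
        feature_sets["clinical_lasso"] = (clin_features[clin_selected],
                                          clin_labels)
        integ = integrate_features(
            wst_amlr, clin_features[clin_selected],
            patient_of=patient_of.loc[wst_amlr.index])
        feature_sets["integrated"] = ear_bundle(integ)

    specs = [ModelSpec(kind, seed=config["seed"]) for kind in config["models"]]
    table, reports = benchmark(feature_sets, specs, folds=config["folds"],
                               seed=config["seed"])
    table.to_csv(out / "benchmark.csv", index=False)
    if config.get("plots", True):
        (out / "plots").mkdir(exist_ok=True)
        for _, row in table[table["best_in_set"]].iterrows():
            rep = reports[(row["feature_set"], row["classifier"])]
            export_roc(rep, out / "plots" / f"roc_{row['feature_set']}.png",
                       title=f"{row['feature_set']} — best: {row['classifier']}")
    return {"artifacts": [out / "benchmark.csv"], "table": table}


# ------------------------------------------------------------------ driver

_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "annotate": stage_annotate,
    "stats": stage_stats,
    "scatter": stage_scatter,
    "clinical": stage_clinical,
    "select": stage_select,
}


def run_stage(name: str, config: dict) -> list[Path]:
    config = merge_config(config)
    if name == "classify":
        return stage_classify(config)["artifacts"]
    if name not in _STAGE_FUNCS:
        raise ConfigurationError(f"unknown stage {name!r}")
    return _STAGE_FUNCS[name](config)


def run_pipeline(config: dict | None = None) -> dict:
    """Execute all stages and write the run manifest.

    Returns the manifest dict (also written to ``manifest.json`` in the
    run directory).  Any stage error aborts the run with the stage name in
    the raised message.
    """
    config = merge_config(config)
    out = _outdir(config)
    import sklearn

    manifest = {
        "config": {k: v for k, v in config.items()},
        "versions": {"aepkit": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "sklearn": sklearn.__version__},
        "stages": [],
        "hashes": {},
    }
    for name in STAGES:
        try:
            if name == "classify":
                artifacts = stage_classify(config)["artifacts"]
            else:
                artifacts = _STAGE_FUNCS[name](config)
        except Exception as exc:
            manifest["stages"].append({"stage": name, "status": "failed",
                                       "error": str(exc)})
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                          default=str))
            raise DataError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"stage": name, "status": "completed"})
        for path in artifacts:
            manifest["hashes"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    logger.info("pipeline complete: %d stages, manifest at %s",
                len(STAGES), out / "manifest.json")
    return manifest
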