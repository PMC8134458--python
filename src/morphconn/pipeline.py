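"""End-to-end orchestration: simulate → networks → metrics → compare → predict.

Each stage is a plain function usable on its own; :func:`run_pipeline`
chains them, stamps every output table with the config hash, logs
per-stage seeds and counts, and writes a manifest of all outputs. A
stage failure aborts with the stage name while keeping the outputs of
completed stages on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import SubjectProfile, clinical_table, generate_cohort
from .config import RunConfig
from .inference import (
    abnormal_regions,
    change_correlation,
    classify_responder,
    fdr_adjust,
    interaction_model,
    permutation_test,
    permutation_test_matrix,
)
from .io import write_cohort, write_matrices_h5, write_table
from .prediction import (
    cross_validated_classification,
    nodal_weight_ranking,
    permutation_significance,
    vectorize_connectome,
)
from .similarity import SimilarityMatrix, build_similarity_matrix
from .topology import ThresholdScheme, global_metric_curves, nodal_metric_curves

logger = logging.getLogger(__name__)

GLOBAL_METRICS_PLAIN = ("cp", "lp", "eglob", "eloc")


def stage_networks(profiles: Sequence[SubjectProfile]) -> list[SimilarityMatrix]:
    """KLS similarity matrix for every subject-timepoint profile."""
    return [build_similarity_matrix(p) for p in profiles]


def stage_metrics(
    matrices: Sequence[SimilarityMatrix],
    scheme: ThresholdScheme,
    clinical: pd.DataFrame,
    n_nulls: int = 100,
    seed: int = 0,
    small_world: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AUC tables for global and nodal metrics, one row per measurement."""
    meta = clinical.set_index(["subject_id", "timepoint"])
    g_rows, n_rows = [], []
    for k, m in enumerate(matrices):
        group = str(meta.loc[(m.subject_id, m.timepoint), "group"])
        curves = global_metric_curves(
            m,
            scheme,
            n_nulls=n_nulls if small_world else 0,
            seed=seed + k,
            metrics=GLOBAL_METRICS_PLAIN,
        )
        for name, curve in curves.items():
            g_rows.append(
                {
                    "subject_id": m.subject_id,
                    "timepoint": m.timepoint,
                    "group": group,
                    "metric": name,
                    "auc": curve.auc,
                }
            )
        nodal = nodal_metric_curves(m, scheme)
        for name, per_region in nodal.items():
            for r, v in enumerate(per_region):
                n_rows.append(
                    {
                        "subject_id": m.subject_id,
                        "timepoint": m.timepoint,
                        "group": group,
                        "metric": name,
                        "region": m.region_labels[r],
                        "auc": float(v),
                    }
                )
    return pd.DataFrame(g_rows), pd.DataFrame(n_rows)


def stage_compare(
    global_auc: pd.DataFrame,
    nodal_auc: pd.DataFrame,
    clinical: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    correlate_metrics: tuple[str, ...] = ("cp", "lp"),
) -> dict[str, pd.DataFrame]:
    """Group inference: AUC permutation tests, the 2-of-3 nodal rule,
    group-by-time mixed models, and symptom-change correlations."""
    out: dict[str, pd.DataFrame] = {}
    timepoints = list(dict.fromkeys(clinical["timepoint"]))

    # --- global AUC permutation tests per timepoint -----------------------
    rows = []
    for tp in timepoints:
        sub = global_auc[global_auc["timepoint"] == tp]
        for metric, chunk in sub.groupby("metric"):
            a = chunk.loc[chunk["group"] == "patient", "auc"].to_numpy()
            b = chunk.loc[chunk["group"] == "control", "auc"].to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            res = permutation_test(a, b, n_perm=n_perm, seed=seed)
            rows.append(
                {
                    "timepoint": tp,
                    "metric": metric,
                    "observed_diff": res.observed,
                    "p": res.p_two_tailed,
                }
            )
    out["global_tests"] = pd.DataFrame(rows)

    # --- nodal centralities: per-region p-values and 2-of-3 flags ---------
    flag_frames = []
    for tp in timepoints:
        sub = nodal_auc[nodal_auc["timepoint"] == tp]
        if sub.empty:
            continue
        wide = sub.pivot_table(
            index=["subject_id", "group"], columns=["metric", "region"], values="auc"
        )
        if wide.empty:
            continue
        mask = wide.index.get_level_values("group") == "patient"
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        _, p = permutation_test_matrix(wide.to_numpy(), mask, n_perm=n_perm, seed=seed)
        p_ser = pd.Series(p, index=wide.columns)
        p_tab = p_ser.unstack(level="metric").rename_axis(index="region")
        p_tab = p_tab.reindex(columns=["degree", "efficiency", "betweenness"])
        flags = abnormal_regions(p_tab.reset_index())
        flags.insert(0, "timepoint", tp)
        flag_frames.append(flags)
    out["nodal_flags"] = (
        pd.concat(flag_frames, ignore_index=True) if flag_frames else pd.DataFrame()
    )

    # --- group-by-time mixed models ---------------------------------------
    rows = []
    clin_ix = clinical.set_index(["subject_id", "timepoint"])
    if len(timepoints) >= 2:
        for metric, chunk in global_auc.groupby("metric"):
            tbl = chunk.merge(
                clinical[["subject_id", "timepoint", "age", "sex"]],
                on=["subject_id", "timepoint"],
            ).rename(columns={"auc": "value"})
            try:
                res = interaction_model(tbl)
            except Exception as exc:  # singular fits on tiny cohorts
                logger.warning("interaction model failed for %s: %s", metric, exc)
                continue
            rows.append({"metric": metric, "effect": res.effect, "F": res.F, "p": res.p})
    inter = pd.DataFrame(rows)
    if not inter.empty:
        inter["q"] = fdr_adjust(inter["p"].to_numpy())
    out["interactions"] = inter

    # --- metric-change vs YMRS-change correlations -------------------------
    rows = []
    if len(timepoints) >= 2:
        t0, t1 = timepoints[0], timepoints[-1]
        pat = clinical[clinical["group"] == "patient"]
        ids = sorted(
            set(pat.loc[pat["timepoint"] == t0, "subject_id"])
            & set(pat.loc[pat["timepoint"] == t1, "subject_id"])
        )
        if len(ids) >= 3:
            d_ymrs = np.array(
                [
                    clin_ix.loc[(s, t0), "ymrs"] - clin_ix.loc[(s, t1), "ymrs"]
                    for s in ids
                ],
                dtype=float,
            )
            gix = global_auc.set_index(["subject_id", "timepoint", "metric"])["auc"]
            for metric in correlate_metrics:
                try:
                    d_m = np.array(
                        [gix.loc[(s, t0, metric)] - gix.loc[(s, t1, metric)] for s in ids]
                    )
                    r, p = change_correlation(d_m, d_ymrs)
                except (KeyError, ValueError) as exc:
                    logger.warning("change correlation skipped for %s: %s", metric, exc)
                    continue
                rows.append({"metric": metric, "r": r, "p": p, "n": len(ids)})
    corr = pd.DataFrame(rows)
    if not corr.empty:
        corr["q"] = fdr_adjust(corr["p"].to_numpy())
    out["change_correlations"] = corr
    return out


def stage_predict(
    matrices: Sequence[SimilarityMatrix],
    clinical: pd.DataFrame,
    n_folds: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> dict:
    """Baseline-connectome SVM prediction of responder status."""
    timepoints = list(dict.fromkeys(clinical["timepoint"]))
    t0, t_end = timepoints[0], timepoints[-1]
    clin_ix = clinical.set_index(["subject_id", "timepoint"])
    feats, labels, ids = [], [], []
    for m in matrices:
        if m.timepoint != t0:
            continue
        try:
            row0 = clin_ix.loc[(m.subject_id, t0)]
            row1 = clin_ix.loc[(m.subject_id, t_end)]
        except KeyError:
            continue  # non-completer
        if str(row0["group"]) != "patient":
            continue
        feats.append(vectorize_connectome(m).values)
        labels.append(classify_responder(float(row0["ymrs"]), float(row1["ymrs"])) == "responder")
        ids.append(m.subject_id)
    X = np.stack(feats)
    y = np.array(labels)
    report = cross_validated_classification(
        X, y, seed=seed, n_folds=n_folds, C=C, region_names=matrices[0].region_labels
    )
    if n_perm > 0:
        report.permutation_p = permutation_significance(
            X, y, n_perm=n_perm, seed=seed, n_folds=n_folds, C=C
        )
    ranking = nodal_weight_ranking(report, top=None)
    return {"report": report, "ranking": ranking, "subject_ids": ids}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, write_samples: bool = False) -> dict:
    """Execute the full analysis and return the output manifest."""
    cfg = config
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    h = cfg.config_hash
    manifest: dict = {"provenance": cfg.provenance(), "outputs": {}}
    stage = "simulate"
    try:
        cohort_cfg = cfg.cohort.with_(seed=cfg.stage_seed("simulate"))
        logger.info("stage simulate: seed=%d", cohort_cfg.seed)
        profiles = generate_cohort(cohort_cfg)
        clinical = clinical_table(profiles)
        paths = [write_table(clinical, os.path.join(out, "clinical.csv"), h)]
        if write_samples:
            paths.append(write_cohort(profiles, out, h)["samples"])
        manifest["outputs"][stage] = paths

        stage = "build-networks"
        matrices = stage_networks(profiles)
        mat_path = write_matrices_h5(matrices, os.path.join(out, "matrices.h5"))
        manifest["outputs"][stage] = [mat_path]

        stage = "metrics"
        scheme = cfg.scheme()
        global_auc, nodal_auc = stage_metrics(
            matrices,
            scheme,
            clinical,
            n_nulls=cfg.n_nulls,
            seed=cfg.stage_seed("metrics"),
            small_world=cfg.small_world,
        )
        manifest["outputs"][stage] = [
            write_table(global_auc, os.path.join(out, "global_auc.csv"), h),
            write_table(nodal_auc, os.path.join(out, "nodal_auc.csv"), h),
        ]

        stage = "compare"
        tables = stage_compare(
            global_auc,
            nodal_auc,
            clinical,
            n_perm=cfg.n_perm_group,
            seed=cfg.stage_seed("compare"),
        )
        manifest["outputs"][stage] = [
            write_table(df, os.path.join(out, f"{name}.csv"), h)
            for name, df in tables.items()
        ]

        if cfg.predict:
            stage = "predict"
            pred = stage_predict(
                matrices,
                clinical,
                n_folds=cfg.n_folds,
                n_perm=cfg.n_perm_svm,
                seed=cfg.stage_seed("predict"),
                C=cfg.svm_C,
            )
            rep = pred["report"]
            summary = {
                "mean_balanced_accuracy": rep.mean_balanced_accuracy,
                "fold_balanced_accuracies": rep.fold_balanced_accuracies.tolist(),
                "permutation_p": rep.permutation_p,
                "top_regions": list(rep.top_regions),
                "n_subjects": len(pred["subject_ids"]),
                "config_hash": h,
            }
            pred_path = os.path.join(out, "prediction.json")
            with open(pred_path, "w") as fh:
                json.dump(summary, fh, indent=2)
            manifest["outputs"][stage] = [
                pred_path,
                write_table(pred["ranking"], os.path.join(out, "nodal_weights.csv"), h),
            ]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest["files"] = {
        p: _sha256(p) for paths in manifest["outputs"].values() for p in paths
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
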