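"""End-to-end pipeline: manifest -> habitats -> 52 features -> classification.

Per subject: GMM habitat masks, 28 MST branch-length features and 24 GRLM
features are computed; per-subject failures (degenerate ROIs, collinear
centroid geometry) are logged and recorded as missing rows, never fatal. When
binary labels are present in the manifest, the feature table is evaluated with
the cross-validated random-forest/ROC harness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierReport, evaluate_features
from .config import PipelineConfig
from .errors import HabitatGraphError
from .grlm import GRLM_FEATURE_NAMES, subject_grlm_features
from .habitats import SlicePair, make_habitat_masks
from .io import read_subject
from .mst_features import MST_FEATURE_NAMES, subject_mst_features

__all__ = ["FEATURE_COLUMNS", "subject_features", "run_pipeline", "PipelineResult"]

#: stable feature-table column order: 28 MST then 24 GRLM features
FEATURE_COLUMNS = list(MST_FEATURE_NAMES) + list(GRLM_FEATURE_NAMES)


@dataclass
class PipelineResult:
    features: pd.DataFrame  # subjects x 52, indexed by subject_id
    labels: pd.Series | None
    report: ClassifierReport | None
    log: list


def subject_features(slices: SlicePair, config: PipelineConfig) -> tuple[dict, dict]:
    """All 52 features for one subject, plus a structured log record."""
    masks = make_habitat_masks(slices, seed=config.gmm_seed)
    features = subject_mst_features(masks, grid_spacing=config.grid_spacing_pixels)
    try:
        features.update(
            subject_grlm_features(
                masks,
                grid_spacing=config.grid_spacing_pixels,
                window_radius_mm=config.window_radius_mm,
                l_max=config.l_max,
            )
        )
    except HabitatGraphError as exc:
        features.update({name: np.nan for name in GRLM_FEATURE_NAMES})
        grlm_warning = str(exc)
    else:
        grlm_warning = None
    record = {
        "subject_id": slices.subject_id,
        "gmm_threshold_t1": masks.gmm_threshold_t1,
        "gmm_threshold_t2": masks.gmm_threshold_t2,
        "n_missing_features": int(sum(np.isnan(v) for v in features.values())),
        "grlm_warning": grlm_warning,
    }
    return features, record


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full feature pipeline over a cohort manifest.

    ``manifest`` is a DataFrame (or CSV path) with columns subject_id, t1c,
    flair, roi_t1, roi_flair and optionally label. If ``out_dir`` is given,
    features.csv, report.json, config.yaml and log.jsonl are written there.
    ``seed`` overrides both the GMM and RF seeds for convenience.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config.gmm_seed = int(seed)
        config.rf_seed = int(seed)
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    rows, log = [], []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        try:
            slices = read_subject(
                {k: row[k] for k in ("t1c", "flair", "roi_t1", "roi_flair")},
                spacing_mm=config.spacing_mm,
                slice_selection=config.slice_selection,
                subject_id=sid,
            )
            features, record = subject_features(slices, config)
        except HabitatGraphError as exc:
            features = {name: np.nan for name in FEATURE_COLUMNS}
            record = {"subject_id": sid, "error": str(exc)}
        rows.append({"subject_id": sid, **features})
        log.append(record)
    table = pd.DataFrame(rows).set_index("subject_id")[FEATURE_COLUMNS]
    labels = None
    report = None
    if "label" in manifest.columns and manifest["label"].notna().all():
        labels = pd.Series(
            manifest["label"].astype(int).to_numpy(),
            index=manifest["subject_id"].astype(str),
            name="label",
        )
        if labels.nunique() == 2:
            try:
                report = evaluate_features(
                    table,
                    labels.loc[table.index],
                    n_trees=config.rf_trees,
                    k=config.cv_folds,
                    seed=config.rf_seed,
                )
            except HabitatGraphError as exc:
                log.append({"classification_skipped": str(exc)})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out = table.copy()
        if labels is not None:
            out["label"] = labels.loc[out.index]
        out.to_csv(out_dir / "features.csv")
        config.to_yaml(out_dir / "config.yaml")
        with open(out_dir / "log.jsonl", "w") as fh:
            for record in log:
                fh.write(json.dumps(record) + "\n")
        if report is not None:
            with open(out_dir / "report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            roc = pd.DataFrame({"fpr": report.roc_fpr, "tpr": report.roc_tpr})
            roc.to_csv(out_dir / "roc_curve.csv", index=False)
    return PipelineResult(features=table, labels=labels, report=report, log=log)
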