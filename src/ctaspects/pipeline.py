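"""Batch orchestration: manifest-driven runs of the pipeline stages.

Each stage is a plain function over files and tables so it can be driven
from Python or from the thin CLI. Batches are described by a manifest CSV
(one row per patient with file paths and the occlusion side); per-patient
failures are logged and collected, and the run continues.

Stage outputs are deterministic given the same inputs, config and seed;
reports embed the config, seed and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AspectsAtlas, Hemisphere, Region, RegionId, load_atlas
from .labels import dwi_aspects, infarct_volume_ml, label_regions, labels_to_frame
from .model import (
    CutPointModel,
    cross_validate,
    fit,
    predict_region,
    region_metrics,
)
from .rhu import compute_rhu, measurements_to_frame
from .stats import (
    compare_dependent_correlations,
    outcome_auc,
    delong_test,
    spearman_ci,
    threshold_aspects,
)
from .volumes import AffineTransform, read_affine, read_volume, resample_mask

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_extract",
    "run_label",
    "run_train",
    "run_evaluate",
    "score_threshold_aspects",
    "import_xlsx",
]


@dataclass
class RunConfig:
    """Run parameters; defaults are the published pipeline settings."""

    hu_min: float = 1.0
    hu_max: float = 250.0
    overlap_threshold: float = 0.30
    k: int = 10
    seed: int = 0
    bootstrap_reps: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


def _resample_atlas(
    atlas: AspectsAtlas, reference, transform: AffineTransform
) -> AspectsAtlas:
    masks = {
        rid: resample_mask(atlas[rid], reference, transform) for rid in atlas
    }
    return AspectsAtlas(masks=masks, template_name=f"{atlas.template_name}->subject")


def _load_transform(path: str | None) -> AffineTransform:
    if path is None or (isinstance(path, float) and np.isnan(path)) or path == "":
        return AffineTransform.identity()
    return read_affine(path)


def run_extract(
    manifest: pd.DataFrame, atlas: AspectsAtlas, config: RunConfig | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """rHU extraction over a manifest with columns
    ``patient_id, cta_path, occlusion_side[, transform_path]``.

    Returns the measurement table (10 rows per patient) and a list of
    per-patient failures ``{patient_id, error}``.
    """
    config = config or RunConfig()
    frames, failures = [], []
    for row in manifest.to_dict("records"):
        pid = str(row["patient_id"])
        try:
            cta = read_volume(row["cta_path"])
            transform = _load_transform(row.get("transform_path"))
            atlas_subj = _resample_atlas(atlas, cta, transform)
            meas = compute_rhu(
                cta,
                atlas_subj,
                row["occlusion_side"],
                patient_id=pid,
                hu_min=config.hu_min,
                hu_max=config.hu_max,
            )
            frames.append(measurements_to_frame(meas))
        except Exception as exc:  # noqa: BLE001 - batch keeps going
            logger.error("extract failed for %s: %s", pid, exc)
            failures.append({"patient_id": pid, "error": str(exc)})
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else measurements_to_frame([])
    )
    return table, failures


def run_label(
    manifest: pd.DataFrame, atlas: AspectsAtlas, config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Infarct labelling over a manifest with columns
    ``patient_id, dwi_lesion_path, occlusion_side[, transform_path]``.

    Returns (region labels, patient summary with dwi_aspects and
    infarct_volume_ml, failures).
    """
    config = config or RunConfig()
    label_frames, patient_rows, failures = [], [], []
    for row in manifest.to_dict("records"):
        pid = str(row["patient_id"])
        try:
            lesion = read_volume(row["dwi_lesion_path"])
            transform = _load_transform(row.get("transform_path"))
            atlas_subj = _resample_atlas(atlas, lesion, transform)
            labels = label_regions(
                atlas_subj,
                lesion,
                row["occlusion_side"],
                threshold=config.overlap_threshold,
                patient_id=pid,
            )
            label_frames.append(labels_to_frame(labels))
            patient_rows.append(
                {
                    "patient_id": pid,
                    "occlusion_side": str(row["occlusion_side"]),
                    "dwi_aspects": dwi_aspects(labels),
                    "infarct_volume_ml": infarct_volume_ml(lesion),
                }
            )
        except Exception as exc:  # noqa: BLE001
            logger.error("label failed for %s: %s", pid, exc)
            failures.append({"patient_id": pid, "error": str(exc)})
    labels_table = (
        pd.concat(label_frames, ignore_index=True) if label_frames else pd.DataFrame()
    )
    return labels_table, pd.DataFrame(patient_rows), failures


def run_train(
    table: pd.DataFrame, config: RunConfig | None = None
) -> tuple[CutPointModel, "pd.DataFrame", dict]:
    """Fit cut points on the full table and cross-validate.

    Returns (model, per-fold metrics table, report dict ready for JSON).
    """
    config = config or RunConfig()
    model = fit(table)
    model.seed = config.seed
    cv = cross_validate(table, k=config.k, seed=config.seed)
    report = {
        "config": config.as_dict(),
        "software_version": __version__,
        "cutpoints": {r.value: t for r, t in model.cutpoints.items()},
        "youden_j": {r.value: j for r, j in model.youden_j.items()},
        "cross_validation": {
            "k": cv.k,
            "seed": cv.seed,
            "aggregate": {
                name: {"mean": mean, "sd": sd}
                for name, (mean, sd) in cv.aggregate.items()
            },
            "n_undefined_cells": cv.n_undefined,
        },
    }
    return model, cv.per_fold, report


def score_threshold_aspects(
    table: pd.DataFrame, model: CutPointModel
) -> pd.DataFrame:
    """Threshold-based ASPECTS per patient from an rHU table."""
    rows = []
    for pid, sub in table.groupby("patient_id", sort=True):
        preds = [
            predict_region(float(r.rhu), model, Region(r.region))
            for r in sub.itertuples()
        ]
        if len(preds) != 10:
            raise ValueError(f"patient {pid}: expected 10 regions, got {len(preds)}")
        rows.append({"patient_id": pid, "threshold_aspects": threshold_aspects(preds)})
    return pd.DataFrame(rows)


def _median_iqr(values: "pd.Series") -> dict[str, float]:
    q1, med, q3 = np.percentile(values.dropna(), [25, 50, 75])
    return {"median": float(med), "iqr_low": float(q1), "iqr_high": float(q3)}


def run_evaluate(
    model: CutPointModel,
    validation: pd.DataFrame,
    patients: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Validate a fitted model on a held-out region table.

    ``validation`` needs ``patient_id, region, rhu, infarcted``. If a
    ``patients`` table is given, patient-level statistics are added for
    whichever of its columns are present — ``dwi_aspects`` (Spearman),
    ``infarct_volume_ml`` (Spearman), ``visual_aspects`` (dependent-
    correlation comparison) and ``poor_outcome`` (outcome AUC + DeLong
    comparison). Missing columns mark their section ``"skipped"``.
    """
    config = config or RunConfig()
    per_region = []
    for region in Region:
        sub = validation[validation["region"] == region.value]
        m = region_metrics(
            sub["rhu"].to_numpy(),
            sub["infarcted"].to_numpy(),
            model.cutpoints[region],
            region=region,
        )
        row = m.as_dict()
        row["cutpoint"] = model.cutpoints[region]
        per_region.append(row)
    metrics = pd.DataFrame(per_region)[
        [
            "region",
            "cutpoint",
            "auc",
            "accuracy",
            "sensitivity",
            "specificity",
            "n_positive",
            "n_negative",
        ]
    ]

    report: dict[str, Any] = {
        "config": config.as_dict(),
        "software_version": __version__,
        "per_region_summary": {
            name: _median_iqr(metrics[name])
            for name in ("auc", "accuracy", "sensitivity", "specificity")
        },
        "notices": [],
    }

    scored = score_threshold_aspects(validation, model)
    if patients is None:
        patients = pd.DataFrame({"patient_id": scored["patient_id"]})
    merged = scored.merge(patients, on="patient_id", how="left", validate="1:1")
    ta = merged["threshold_aspects"].to_numpy(dtype=float)

    def _spearman_section(column: str) -> dict | str:
        if column not in merged or merged[column].isna().all():
            report["notices"].append(f"no {column} column: correlation skipped")
            return "skipped"
        vals = merged[column].to_numpy(dtype=float)
        res = spearman_ci(ta, vals, config.bootstrap_reps, seed=config.seed)
        return {
            "r_s": res.r_s,
            "ci": [res.ci_low, res.ci_high],
            "p_value": res.p_value,
            "n": res.n,
        }

    report["spearman_vs_dwi_aspects"] = _spearman_section("dwi_aspects")
    report["spearman_vs_infarct_volume"] = _spearman_section("infarct_volume_ml")

    if "visual_aspects" in merged and "dwi_aspects" in merged and not (
        merged["visual_aspects"].isna().any() or merged["dwi_aspects"].isna().any()
    ):
        va = merged["visual_aspects"].to_numpy(dtype=float)
        dwi = merged["dwi_aspects"].to_numpy(dtype=float)
        report["visual_vs_threshold"] = {
            "p_dwi_aspects": compare_dependent_correlations(
                va, ta, dwi, config.bootstrap_reps, seed=config.seed
            )
        }
        if "infarct_volume_ml" in merged and not merged["infarct_volume_ml"].isna().any():
            report["visual_vs_threshold"]["p_infarct_volume"] = (
                compare_dependent_correlations(
                    va,
                    ta,
                    merged["infarct_volume_ml"].to_numpy(dtype=float),
                    config.bootstrap_reps,
                    seed=config.seed,
                )
            )
    else:
        report["visual_vs_threshold"] = "skipped"
        report["notices"].append("no visual_aspects column: comparison skipped")

    if "poor_outcome" in merged and not merged["poor_outcome"].isna().any():
        poor = merged["poor_outcome"].to_numpy(dtype=bool)
        auc_val, ci = outcome_auc(ta, poor)
        section: dict[str, Any] = {"threshold_aspects": {"auc": auc_val, "ci": list(ci)}}
        if "visual_aspects" in merged and not merged["visual_aspects"].isna().any():
            va = merged["visual_aspects"].to_numpy(dtype=float)
            auc_v, ci_v = outcome_auc(va, poor)
            cmp = delong_test(10.0 - ta, 10.0 - va, poor)
            section["visual_aspects"] = {"auc": auc_v, "ci": list(ci_v)}
            section["delong_p"] = cmp.p_value
        report["outcome"] = section
    else:
        report["outcome"] = "skipped"
        report["notices"].append("no poor_outcome column: outcome section skipped")

    return metrics, report


def import_xlsx(
    path: str | Path, mapping: dict, sheet: str | int = 0
) -> pd.DataFrame:
    """Import a deposited measurement workbook into the tidy region table.

    ``mapping`` is a column-mapping config because workbook layouts vary:
    ``{"patient_id": <col>, "region": <col>, "rhu": <col>, "infarcted": <col>,
    "region_names": {<sheet value>: <Region name>, ...}}``. The optional
    ``region_names`` entry normalises spellings (e.g. "Internal Capsular")
    to the canonical identifiers.
    """
    raw = pd.read_excel(path, sheet_name=sheet)
    required = ("patient_id", "region", "rhu", "infarcted")
    missing = [k for k in required if k not in mapping]
    if missing:
        raise ValueError(f"mapping missing keys: {missing}")
    out = pd.DataFrame(
        {key: raw[mapping[key]] for key in required}
    )
    renames = {str(k): v for k, v in mapping.get("region_names", {}).items()}
    if renames:
        out["region"] = out["region"].astype(str).map(lambda s: renames.get(s, s))
    bad = set(out["region"]) - {r.value for r in Region}
    if bad:
        raise ValueError(f"unrecognised region names after mapping: {sorted(bad)}")
    out["infarcted"] = out["infarcted"].astype(bool)
    out["patient_id"] = out["patient_id"].astype(str)
    return out


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
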