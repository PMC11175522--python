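"""Per-region Youden-optimal rHU cut points and their evaluation.

Each ASPECTS region gets its own threshold on the relative Hounsfield unit:
a region is predicted to infarct when its rHU falls strictly below the cut
point (hypo-attenuation relative to the mirror region). The cut point is
chosen to maximise the Youden index J = sensitivity + specificity - 1 on
the training cohort; model stability is measured with single-round k-fold
cross-validation at the patient level.

Orientation is fixed throughout this module: a LOW score marks the positive
(infarcted) class. AUC is the Mann-Whitney probability that a random
positive scores lower than a random negative, ties counted half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Region

__all__ = [
    "CutPointModel",
    "RegionMetrics",
    "CrossValReport",
    "SingleClassError",
    "youden_cutpoint",
    "predict_region",
    "auc",
    "region_metrics",
    "fit",
    "cross_validate",
]

METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity")


class SingleClassError(ValueError):
    """Both classes are required (for a cut point or an AUC)."""


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    if s.size == 0:
        raise ValueError("empty input")
    return s, y


def youden_cutpoint(scores, labels) -> tuple[float, float]:
    """Threshold maximising J = sensitivity + specificity - 1.

    The decision rule is "predict infarcted iff score < t". Candidate
    thresholds are the midpoints between consecutive distinct observed
    scores, plus the two trivial boundaries (predict none / predict all);
    ties in J are broken toward the smallest threshold. Returns ``(t, J)``.
    """
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("need at least one positive and one negative")
    distinct = np.unique(s)
    candidates = np.concatenate(
        [[distinct[0]], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    # predict positive iff score < t; J is scored on integer counts
    # (tp*n_neg + tn*n_pos) so that exact ties stay exact ties
    tp = np.searchsorted(np.sort(s[y]), candidates, side="left")
    tn = n_neg - np.searchsorted(np.sort(s[~y]), candidates, side="left")
    j_scaled = tp * n_neg + tn * n_pos - n_pos * n_neg
    best = int(np.argmax(j_scaled))  # first maximum = smallest t on ties
    return float(candidates[best]), float(j_scaled[best] / (n_pos * n_neg))


def predict_region(rhu: float, model: "CutPointModel", region: Region | str) -> bool:
    """Predict final infarction: rHU strictly below the region's cut point."""
    region = Region(region)
    if region not in model.cutpoints:
        raise KeyError(f"no cut point for region {region}")
    return bool(rhu < model.cutpoints[region])


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with 'low score = positive class' orientation.

    Probability that a uniformly random positive has a lower score than a
    uniformly random negative; ties contribute 1/2.
    """
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC needs both classes")
    ranks = stats.rankdata(s)  # average ranks handle ties
    # P(pos > neg) + ties/2, then flip for the low-is-positive orientation
    auc_high = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(1.0 - auc_high)


@dataclass(frozen=True)
class RegionMetrics:
    """Confusion-matrix metrics for one region at one threshold.

    Metrics that are undefined because a class is absent are NaN and listed
    in ``undefined`` rather than silently zeroed.
    """

    region: Region | None
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    n_positive: int
    n_negative: int
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "region": self.region.value if self.region else None,
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def region_metrics(scores, labels, threshold: float, region: Region | None = None) -> RegionMetrics:
    """AUC, accuracy, sensitivity and specificity under the strict-below rule."""
    s, y = _as_arrays(scores, labels)
    pred = s < threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    undefined = []
    if n_pos and n_neg:
        auc_val = auc(s, y)
    else:
        auc_val = float("nan")
        undefined.append("auc")
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    if not n_pos:
        undefined.append("sensitivity")
    if not n_neg:
        undefined.append("specificity")
    return RegionMetrics(
        region=region,
        auc=auc_val,
        accuracy=(tp + tn) / s.size,
        sensitivity=sens,
        specificity=spec,
        n_positive=n_pos,
        n_negative=n_neg,
        undefined=tuple(undefined),
    )


@dataclass
class CutPointModel:
    """One optimal rHU threshold per ASPECTS region."""

    cutpoints: dict[Region, float]
    training_n: dict[Region, int] = field(default_factory=dict)
    youden_j: dict[Region, float] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        from . import __version__

        payload = {
            "cutpoints": {r.value: t for r, t in self.cutpoints.items()},
            "training_n": {r.value: n for r, n in self.training_n.items()},
            "youden_j": {r.value: j for r, j in self.youden_j.items()},
            "software_version": __version__,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CutPointModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            cutpoints={Region(r): float(t) for r, t in payload["cutpoints"].items()},
            training_n={Region(r): int(n) for r, n in payload.get("training_n", {}).items()},
            youden_j={Region(r): float(j) for r, j in payload.get("youden_j", {}).items()},
            seed=payload.get("seed"),
        )


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"patient_id", "region", "rhu", "infarcted"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"training table missing columns: {sorted(missing)}")
    return table


def fit(training: pd.DataFrame) -> CutPointModel:
    """Fit one Youden-optimal cut point per region.

    ``training`` has one row per patient x region with columns
    ``patient_id, region, rhu, infarcted``. Regions with a single class are
    collected and reported together in one error.
    """
    table = _check_table(training)
    cutpoints: dict[Region, float] = {}
    training_n: dict[Region, int] = {}
    youden: dict[Region, float] = {}
    single_class: list[str] = []
    for region in Region:
        sub = table[table["region"] == region.value]
        if sub.empty:
            single_class.append(f"{region} (no rows)")
            continue
        try:
            t, j = youden_cutpoint(sub["rhu"].to_numpy(), sub["infarcted"].to_numpy())
        except SingleClassError:
            single_class.append(region.value)
            continue
        cutpoints[region] = t
        training_n[region] = len(sub)
        youden[region] = j
    if single_class:
        raise SingleClassError(
            "regions without both classes: " + ", ".join(single_class)
        )
    return CutPointModel(cutpoints=cutpoints, training_n=training_n, youden_j=youden)


@dataclass
class CrossValReport:
    """Single-round k-fold cross-validation summary.

    ``fold_assignments`` maps patient to test fold; ``per_fold`` has one row
    per fold x region with the held-out metrics; ``aggregate`` holds
    mean +/- SD per metric over all region x fold cells, with undefined
    cells (e.g. a fold where a region has no positives) excluded and
    counted in ``n_undefined``.
    """

    k: int
    seed: int | None
    fold_assignments: dict[str, int]
    per_fold: pd.DataFrame
    aggregate: dict[str, tuple[float, float]]
    n_undefined: dict[str, int]

    def summary(self) -> str:
        parts = [
            f"{name} {mean:.2f}+/-{sd:.2f}" for name, (mean, sd) in self.aggregate.items()
        ]
        return f"{self.k}-fold CV (seed={self.seed}): " + ", ".join(parts)


def cross_validate(
    training: pd.DataFrame, k: int = 10, seed: int | None = None
) -> CrossValReport:
    """Patient-level k-fold cross-validation of the cut-point model.

    Patients are randomly partitioned into k folds (unstratified); for each
    fold the cut points are fitted on the other k-1 folds and evaluated on
    the held-out patients, region by region.
    """
    table = _check_table(training)
    patients = np.asarray(sorted(table["patient_id"].unique()))
    if k > patients.size:
        raise ValueError(f"k={k} exceeds number of patients ({patients.size})")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(patients.size)
    assignments = {
        str(patients[idx]): fold
        for fold, chunk in enumerate(np.array_split(order, k))
        for idx in chunk
    }
    fold_of = table["patient_id"].astype(str).map(assignments)

    rows = []
    for fold in range(k):
        train_tab = table[fold_of != fold]
        test_tab = table[fold_of == fold]
        model = fit(train_tab)
        for region in Region:
            sub = test_tab[test_tab["region"] == region.value]
            if sub.empty:
                continue
            m = region_metrics(
                sub["rhu"].to_numpy(),
                sub["infarcted"].to_numpy(),
                model.cutpoints[region],
                region=region,
            )
            rows.append({"fold": fold, **m.as_dict()})
    per_fold = pd.DataFrame(rows)

    aggregate: dict[str, tuple[float, float]] = {}
    n_undefined: dict[str, int] = {}
    for name in METRIC_NAMES:
        cells = per_fold[name].to_numpy(dtype=float)
        valid = cells[~np.isnan(cells)]
        n_undefined[name] = int(np.isnan(cells).sum())
        aggregate[name] = (float(valid.mean()), float(valid.std(ddof=1)))
    return CrossValReport(
        k=k,
        seed=seed,
        fold_assignments=assignments,
        per_fold=per_fold,
        aggregate=aggregate,
        n_undefined=n_undefined,
    )
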