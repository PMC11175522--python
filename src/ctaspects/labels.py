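"""Ground-truth infarct labels from the post-treatment DWI lesion mask.

A region counts as infarcted when at least 30% of its voxels intersect the
manually segmented DWI lesion; the DWI-based ASPECTS is then 10 minus the
number of infarcted regions. The 30% denominator is the region's voxel
count after resampling to the subject DWI grid — the space where the
intersection is computed. The boundary comparison is done on the exact
rational count ratio so that a lesion covering exactly 30% of a region is
infarcted, with no floating-point surprises.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .atlas import AspectsAtlas, Hemisphere, Region, RegionId
from .volumes import Volume3D

__all__ = [
    "RegionLabel",
    "PatientRecord",
    "OVERLAP_THRESHOLD",
    "overlap_fraction",
    "label_regions",
    "infarct_volume_ml",
    "dwi_aspects",
    "labels_to_frame",
]

OVERLAP_THRESHOLD = 0.30


@dataclass(frozen=True)
class RegionLabel:
    patient_id: str
    region: Region
    overlap_fraction: float
    infarcted: bool


@dataclass(frozen=True)
class PatientRecord:
    """Patient-level summary used by the outcome statistics.

    ``poor_outcome`` is a 3-month modified Rankin Scale score above 2.
    ``mrs_imputed_from_discharge`` flags records where the discharge mRS was
    carried forward because the 3-month score was missing (an explicit
    data-preparation flag, not hidden logic).
    """

    patient_id: str
    occlusion_side: Hemisphere
    dwi_aspects: int
    threshold_aspects: int | None = None
    visual_aspects: int | None = None
    infarct_volume_ml: float = 0.0
    mrs_3month: int | None = None
    mrs_imputed_from_discharge: bool = False

    def __post_init__(self) -> None:
        for name in ("dwi_aspects", "threshold_aspects", "visual_aspects"):
            value = getattr(self, name)
            if value is not None and not 0 <= value <= 10:
                raise ValueError(f"{name} must be in 0..10, got {value}")
        if self.mrs_3month is not None and not 0 <= self.mrs_3month <= 6:
            raise ValueError(f"mrs_3month must be in 0..6, got {self.mrs_3month}")

    @property
    def poor_outcome(self) -> bool | None:
        if self.mrs_3month is None:
            return None
        return self.mrs_3month > 2


def overlap_fraction(region_mask: Volume3D, lesion_mask: Volume3D) -> float:
    """|region ∩ lesion| / |region| on a shared grid."""
    for name, m in (("region", region_mask), ("lesion", lesion_mask)):
        if not m.is_binary():
            raise ValueError(f"{name} mask must be binary")
    if not region_mask.same_grid(lesion_mask):
        raise ValueError("region and lesion masks must share one grid")
    region = region_mask.data.astype(bool)
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("region mask is empty")
    n_inter = int((region & lesion_mask.data.astype(bool)).sum())
    return n_inter / n_region


def _is_infarcted(n_inter: int, n_region: int, threshold: float) -> bool:
    # exact rational comparison: 3/10 of 10 voxels is infarcted, not 0.299999..
    return Fraction(n_inter, n_region) >= Fraction(str(threshold))


def label_regions(
    atlas_dwi: AspectsAtlas,
    lesion: Volume3D,
    occlusion_side: Hemisphere | str,
    threshold: float = OVERLAP_THRESHOLD,
    patient_id: str = "",
) -> list[RegionLabel]:
    """Dichotomize each occlusion-side region against the lesion mask.

    ``atlas_dwi`` must be on the DWI grid. Only the 10 regions on the
    occlusion side are labelled (the score is evaluated unilaterally).
    """
    side = Hemisphere(occlusion_side)
    out = []
    for region in Region:
        mask = atlas_dwi[RegionId(region, side)]
        region_vox = mask.data.astype(bool)
        n_region = int(region_vox.sum())
        if n_region == 0:
            raise ValueError(f"region mask empty on DWI grid: {RegionId(region, side)}")
        if not lesion.same_grid(mask):
            raise ValueError("lesion mask must be on the atlas (DWI) grid")
        n_inter = int((region_vox & lesion.data.astype(bool)).sum())
        out.append(
            RegionLabel(
                patient_id=patient_id,
                region=region,
                overlap_fraction=n_inter / n_region,
                infarcted=_is_infarcted(n_inter, n_region, threshold),
            )
        )
    return out


def infarct_volume_ml(lesion: Volume3D) -> float:
    """Lesion volume in millilitres: voxel count x voxel volume / 1000."""
    if not lesion.is_binary():
        raise ValueError("lesion mask must be binary")
    return float(lesion.data.sum()) * lesion.voxel_volume_mm3 / 1000.0


def dwi_aspects(labels: list[RegionLabel]) -> int:
    """ASPECTS from region labels: 10 minus the number of infarcted regions."""
    regions = [lab.region for lab in labels]
    if len(labels) != 10 or len(set(regions)) != 10:
        raise ValueError("expected exactly one label per each of the 10 regions")
    return 10 - sum(bool(lab.infarcted) for lab in labels)


def labels_to_frame(labels: list[RegionLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [l.patient_id for l in labels],
            "region": [l.region.value for l in labels],
            "overlap_fraction": [l.overlap_fraction for l in labels],
            "infarcted": [bool(l.infarcted) for l in labels],
        }
    )
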