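"""Per-region relative Hounsfield units (rHU) from a subject CTA.

rHU of an ASPECTS region is the mean attenuation of the region on the
occluded side divided by the mean attenuation of the mirror region on the
non-occluded side. The ratio normalises away inter-patient differences in
contrast bolus timing; an additional 1-250 HU inclusion window drops air,
bone and dense vessel voxels that leak into a region through imperfect
coregistration. Early irreversible ischemia depresses attenuation on CTA
source images, so infarcting regions show rHU below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AspectsAtlas, Hemisphere, Region, RegionId, contralateral
from .volumes import Volume3D

__all__ = ["RegionMeasurement", "EmptyRegionError", "region_mean_hu", "compute_rhu",
           "measurements_to_frame", "HU_MIN", "HU_MAX"]

HU_MIN = 1.0
HU_MAX = 250.0


class EmptyRegionError(ValueError):
    """A region has no voxels left after the HU inclusion window."""

    def __init__(self, message: str, region: RegionId | None = None):
        super().__init__(message)
        self.region = region


@dataclass(frozen=True)
class RegionMeasurement:
    """One occlusion-side region of one patient.

    ``rhu`` is ipsilateral mean HU over contralateral mean HU, both means
    taken over the same inclusion window; voxel counts record how many
    voxels survived the window on each side.
    """

    patient_id: str
    region: Region
    hemisphere_occluded: Hemisphere
    rhu: float
    ipsi_mean_hu: float
    contra_mean_hu: float
    n_voxels_ipsi: int
    n_voxels_contra: int


def region_mean_hu(
    cta: Volume3D,
    mask: Volume3D,
    hu_min: float = HU_MIN,
    hu_max: float = HU_MAX,
    region: RegionId | None = None,
) -> tuple[float, int]:
    """Mean attenuation over mask voxels inside the [hu_min, hu_max] window.

    Both bounds are inclusive. Returns ``(mean_hu, n_voxels)``; raises
    :class:`EmptyRegionError` if no voxel survives the window.
    """
    if not mask.is_binary():
        raise ValueError("region mask must be binary")
    if not mask.same_grid(cta):
        raise ValueError("mask and CTA must share one grid")
    values = np.asarray(cta.data, dtype=float)[mask.data.astype(bool)]
    values = values[(values >= hu_min) & (values <= hu_max)]
    if values.size == 0:
        raise EmptyRegionError(
            f"empty region after HU filter [{hu_min}, {hu_max}]"
            + (f": {region}" if region else ""),
            region=region,
        )
    return float(values.mean()), int(values.size)


def compute_rhu(
    cta: Volume3D,
    atlas_subject: AspectsAtlas,
    occlusion_side: Hemisphere | str,
    patient_id: str = "",
    hu_min: float = HU_MIN,
    hu_max: float = HU_MAX,
) -> list[RegionMeasurement]:
    """rHU for the 10 ASPECTS regions on the occlusion side.

    ``atlas_subject`` must already be resampled onto the CTA grid. The same
    HU window is applied to the ipsilateral and the contralateral mean.
    """
    side = Hemisphere(occlusion_side)
    out = []
    for region in Region:
        ipsi_id = RegionId(region, side)
        contra_id = contralateral(ipsi_id)
        ipsi_mean, n_ipsi = region_mean_hu(
            cta, atlas_subject[ipsi_id], hu_min, hu_max, region=ipsi_id
        )
        contra_mean, n_contra = region_mean_hu(
            cta, atlas_subject[contra_id], hu_min, hu_max, region=contra_id
        )
        out.append(
            RegionMeasurement(
                patient_id=patient_id,
                region=region,
                hemisphere_occluded=side,
                rhu=ipsi_mean / contra_mean,
                ipsi_mean_hu=ipsi_mean,
                contra_mean_hu=contra_mean,
                n_voxels_ipsi=n_ipsi,
                n_voxels_contra=n_contra,
            )
        )
    return out


def measurements_to_frame(measurements: list[RegionMeasurement]) -> pd.DataFrame:
    """Tabulate measurements with one row per patient x region."""
    return pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in measurements],
            "region": [m.region.value for m in measurements],
            "hemisphere_occluded": [m.hemisphere_occluded.value for m in measurements],
            "rhu": [m.rhu for m in measurements],
            "ipsi_mean_hu": [m.ipsi_mean_hu for m in measurements],
            "contra_mean_hu": [m.contra_mean_hu for m in measurements],
            "n_voxels_ipsi": [m.n_voxels_ipsi for m in measurements],
            "n_voxels_contra": [m.n_voxels_contra for m in measurements],
        }
    )
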