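"""The ASPECTS region atlas: 10 regions x 2 hemispheres of binary masks.

The Alberta Stroke Program Early CT Score deducts one point per affected
middle-cerebral-artery territory region: three subcortical (caudate,
internal capsule, lentiform nucleus) and seven cortical (insular cortex,
M1-M6). The atlas holds one binary mask per region and hemisphere, all on a
single template grid (typically MNI-152). Masks can be loaded from a
directory of 20 NIfTI files or from one integer-label volume with a JSON
sidecar mapping labels to region names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .volumes import Volume3D, read_volume, write_volume

__all__ = [
    "Region",
    "Hemisphere",
    "RegionId",
    "AspectsAtlas",
    "AtlasError",
    "REGIONS",
    "ALL_REGION_IDS",
    "contralateral",
    "load_atlas",
    "save_atlas",
]


class AtlasError(ValueError):
    """Raised when an atlas violates the ASPECTS parcellation contract."""


class Region(str, Enum):
    CAUDATE = "Caudate"
    INTERNAL_CAPSULE = "InternalCapsule"
    LENTIFORM_NUCLEUS = "LentiformNucleus"
    INSULAR_CORTEX = "InsularCortex"
    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"
    M5 = "M5"
    M6 = "M6"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Hemisphere(str, Enum):
    LEFT = "left"
    RIGHT = "right"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def opposite(self) -> "Hemisphere":
        return Hemisphere.RIGHT if self is Hemisphere.LEFT else Hemisphere.LEFT


REGIONS: tuple[Region, ...] = tuple(Region)


@dataclass(frozen=True)
class RegionId:
    """One of the 20 atlas entries: an ASPECTS region in one hemisphere."""

    region: Region
    hemisphere: Hemisphere

    def __str__(self) -> str:
        return f"{self.region.value}_{self.hemisphere.value}"

    @classmethod
    def parse(cls, text: str) -> "RegionId":
        try:
            region_s, hemi_s = text.rsplit("_", 1)
            return cls(Region(region_s), Hemisphere(hemi_s))
        except ValueError as exc:
            raise AtlasError(f"cannot parse region id {text!r}") from exc


ALL_REGION_IDS: tuple[RegionId, ...] = tuple(
    RegionId(r, h) for r in REGIONS for h in Hemisphere
)


def contralateral(region_id: RegionId) -> RegionId:
    """Mirror a region to the opposite hemisphere (an involution)."""
    return RegionId(region_id.region, region_id.hemisphere.opposite)


@dataclass
class AspectsAtlas:
    """Twenty binary region masks on one shared template grid."""

    masks: dict[RegionId, Volume3D]
    template_name: str = "template"

    def __post_init__(self) -> None:
        self.validate()

    def __getitem__(self, key: RegionId) -> Volume3D:
        return self.masks[key]

    def __iter__(self) -> Iterator[RegionId]:
        return iter(self.masks)

    @property
    def grid(self) -> Volume3D:
        return next(iter(self.masks.values()))

    def validate(self) -> None:
        """Check the parcellation contract, reporting all violations at once.

        Required: all 20 regions present, all masks binary and non-empty on
        one shared grid, no overlap between any two masks (midline bleed
        between hemispheres would corrupt the left/right intensity ratio),
        and each region's left and right masks on opposite sides of the
        template midsagittal plane.
        """
        problems: list[str] = []
        missing = [str(r) for r in ALL_REGION_IDS if r not in self.masks]
        if missing:
            problems.append(f"missing regions: {', '.join(missing)}")
        ref = next(iter(self.masks.values()), None)
        for rid, vol in self.masks.items():
            if not vol.is_binary():
                problems.append(f"{rid}: mask is not binary")
            elif not vol.data.any():
                problems.append(f"{rid}: mask is empty")
            if ref is not None and not vol.same_grid(ref):
                problems.append(f"{rid}: grid differs from other masks")
        if not problems:
            ids = list(self.masks)
            stack = np.zeros(ref.shape, dtype=np.int32)
            for rid in ids:
                stack += self.masks[rid].data.astype(np.int32)
            if (stack > 1).any():
                overlapping = [
                    str(rid)
                    for rid in ids
                    if (self.masks[rid].data.astype(bool) & (stack > 1)).any()
                ]
                problems.append(f"overlapping masks: {', '.join(overlapping)}")
            problems.extend(self._check_laterality())
        if problems:
            raise AtlasError("invalid ASPECTS atlas: " + "; ".join(problems))

    def _check_laterality(self) -> list[str]:
        # World x of each mask centroid, against the grid's midsagittal plane.
        ref = self.grid
        centre_idx = (np.asarray(ref.shape, dtype=float) - 1) / 2
        mid_x = (ref.affine @ np.append(centre_idx, 1.0))[0]
        problems = []
        for region in REGIONS:
            sides = {}
            for hemi in Hemisphere:
                vol = self.masks[RegionId(region, hemi)]
                idx = np.argwhere(vol.data > 0)
                centroid = idx.mean(axis=0)
                world = vol.affine @ np.append(centroid, 1.0)
                sides[hemi] = world[0] - mid_x
            if sides[Hemisphere.LEFT] * sides[Hemisphere.RIGHT] >= 0:
                problems.append(
                    f"{region}: left/right masks not on opposite sides of the midsagittal plane"
                )
        return problems


def _mask_filename(rid: RegionId) -> str:
    return f"{rid}.nii.gz"


def load_atlas(path: str | Path, template_name: str = "template") -> AspectsAtlas:
    """Load an atlas from a directory of 20 masks or a label volume.

    Directory layout: one ``<Region>_<hemisphere>.nii.gz`` (or ``.nii``) per
    region. Label-volume layout: a single integer NIfTI plus a JSON sidecar
    ``<stem>_labels.json`` (or ``labels.json`` next to it) mapping label
    integers to ``<Region>_<hemisphere>`` strings.
    """
    path = Path(path)
    if path.is_dir():
        masks: dict[RegionId, Volume3D] = {}
        for rid in ALL_REGION_IDS:
            for ext in (".nii.gz", ".nii"):
                cand = path / f"{rid}{ext}"
                if cand.exists():
                    masks[rid] = read_volume(cand)
                    break
            else:
                raise AtlasError(f"missing mask file for region {rid} in {path}")
        return AspectsAtlas(masks=masks, template_name=template_name)
    return _load_label_volume(path, template_name)


def _sidecar_for(path: Path) -> Path:
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    for cand in (path.parent / f"{stem}_labels.json", path.parent / "labels.json"):
        if cand.exists():
            return cand
    raise AtlasError(f"no label-map sidecar found for {path}")


def _load_label_volume(path: Path, template_name: str) -> AspectsAtlas:
    label_map: Mapping[str, str] = json.loads(_sidecar_for(path).read_text())
    vol = read_volume(path)
    labels = np.rint(vol.data).astype(int)
    masks: dict[RegionId, Volume3D] = {}
    for label_str, rid_str in label_map.items():
        rid = RegionId.parse(rid_str)
        masks[rid] = Volume3D(
            data=(labels == int(label_str)).astype(np.uint8),
            affine=vol.affine.copy(),
        )
    return AspectsAtlas(masks=masks, template_name=template_name)


def save_atlas(atlas: AspectsAtlas, directory: str | Path) -> None:
    """Write the atlas as 20 NIfTI mask files in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rid, vol in atlas.masks.items():
        write_volume(vol, directory / _mask_filename(rid))
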