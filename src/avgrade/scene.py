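"""Co-registered retinal raster containers and their PNG on-disk layout.

A :class:`VesselScene` bundles the rasters the grading pipeline consumes:
the RGB fundus image, the binary vessel mask produced by a segmentation
model, the per-pixel artery/vein label map produced by an A/V classifier,
and an optional optic-cup exclusion mask.  All rasters share one (H, W)
grid with 0-based (row, col) coordinates, origin at the top-left.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: artery/vein map pixel codes
AV_BACKGROUND, AV_ARTERY, AV_VEIN = 0, 1, 2

#: severity grades of venular narrowing at a crossing, in increasing order
GRADES = ("none", "mild", "moderate", "severe")
GRADE_TO_INDEX = {g: i for i, g in enumerate(GRADES)}


@dataclasses.dataclass
class VesselScene:
    """Fundus image plus vessel/artery-vein rasters for one retinal image.

    Parameters
    ----------
    fundus : (H, W, 3) uint8
        RGB fundus image (or synthetic stand-in).
    vessel_mask : (H, W) bool
        Binary vessel segmentation.
    av_map : (H, W) uint8
        Pixel labels: 0 background, 1 artery, 2 vein.
    cup_mask : (H, W) bool or None
        Optic-cup zone where crossing candidates are unreliable.
    """

    fundus: np.ndarray
    vessel_mask: np.ndarray
    av_map: np.ndarray
    cup_mask: np.ndarray | None = None
    subject_id: str = "subject-0"
    image_id: str = "scene-0"

    def __post_init__(self) -> None:
        self.fundus = np.asarray(self.fundus, dtype=np.uint8)
        self.vessel_mask = np.asarray(self.vessel_mask).astype(bool)
        self.av_map = np.asarray(self.av_map, dtype=np.uint8)
        if self.cup_mask is not None:
            self.cup_mask = np.asarray(self.cup_mask).astype(bool)
        shapes = {self.fundus.shape[:2], self.vessel_mask.shape, self.av_map.shape}
        if self.cup_mask is not None:
            shapes.add(self.cup_mask.shape)
        if len(shapes) != 1:
            raise ValueError(f"rasters disagree on (H, W): {sorted(shapes)}")
        if self.fundus.ndim != 3 or self.fundus.shape[2] != 3:
            raise ValueError("fundus must be an (H, W, 3) RGB raster")
        if not np.isin(self.av_map, (AV_BACKGROUND, AV_ARTERY, AV_VEIN)).all():
            raise ValueError("av_map codes must be in {0, 1, 2}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vessel_mask.shape

    def is_refined(self) -> bool:
        """True when no artery/vein label falls outside the vessel mask."""
        return not np.any((self.av_map != AV_BACKGROUND) & ~self.vessel_mask)


def save_scene(scene: VesselScene, directory: str | Path) -> dict[str, Path]:
    """Write a scene as PNG rasters named ``{image_id}_{layer}.png``.

    The A/V map keeps its raw codes {0,1,2}; binary masks are stored as
    {0,255} for viewability.  Returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    stem = scene.image_id
    paths["fundus"] = directory / f"{stem}_fundus.png"
    iio.imwrite(paths["fundus"], scene.fundus)
    paths["vessel"] = directory / f"{stem}_vessel.png"
    iio.imwrite(paths["vessel"], scene.vessel_mask.astype(np.uint8) * 255)
    paths["av"] = directory / f"{stem}_av.png"
    iio.imwrite(paths["av"], scene.av_map)
    if scene.cup_mask is not None:
        paths["cup"] = directory / f"{stem}_cup.png"
        iio.imwrite(paths["cup"], scene.cup_mask.astype(np.uint8) * 255)
    return paths


def load_scene(
    directory: str | Path,
    image_id: str,
    subject_id: str = "subject-0",
    cup_dir: str | Path | None = None,
) -> VesselScene:
    """Load a scene written by :func:`save_scene`.

    ``cup_dir`` may point at a separate directory of cup masks; by default the
    scene directory itself is searched for ``{image_id}_cup.png``.
    """
    directory = Path(directory)
    fundus = iio.imread(directory / f"{image_id}_fundus.png")
    vessel = iio.imread(directory / f"{image_id}_vessel.png") > 127
    av = iio.imread(directory / f"{image_id}_av.png")
    cup_path = Path(cup_dir or directory) / f"{image_id}_cup.png"
    cup = iio.imread(cup_path) > 127 if cup_path.exists() else None
    return VesselScene(
        fundus=fundus,
        vessel_mask=vessel,
        av_map=av,
        cup_mask=cup,
        subject_id=subject_id,
        image_id=image_id,
    )


def write_scene_manifest(path: str | Path, scenes: list[VesselScene]) -> None:
    """Write a ``scenes.csv`` mapping image ids to subject ids."""
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in scenes],
            "image_id": [s.image_id for s in scenes],
        }
    )
    df.to_csv(path, index=False)


def read_scene_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "image_id": str})
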