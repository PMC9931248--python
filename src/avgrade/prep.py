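"""Vessel raster preprocessing: A/V label refinement and skeletonization.

Artery/vein pixel classifiers are noisier than vessel segmenters, so before
crossing detection the per-pixel A/V labels are reconciled with the vessel
mask: labels outside the mask are dropped, and each vessel *segment* (the
stretch between two skeleton branch points) is homogenized to its majority
label.  This removes small mislabelled islands inside an otherwise
consistently labelled vessel while leaving the segmentation itself untouched.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .scene import AV_ARTERY, AV_BACKGROUND, AV_VEIN, VesselScene

_EIGHT = np.ones((3, 3), dtype=int)


@dataclasses.dataclass
class Skeleton:
    """One-pixel-wide medial axis of a vessel mask with per-pixel branch degree."""

    skeleton_mask: np.ndarray  # (H, W) bool
    branch_degree: np.ndarray  # (H, W) uint8; 8-neighbour skeleton pixel count


def skeletonize(mask: np.ndarray) -> Skeleton:
    """Topology-preserving thinning of a binary mask.

    The branch-degree raster counts the 8-connected skeleton neighbours of
    each skeleton pixel: endpoints have degree 1, simple path pixels 2, and
    branch points 3 or more.  An empty mask yields an empty skeleton.
    """
    mask = np.asarray(mask).astype(bool)
    skel = _sk_skeletonize(mask)
    neigh = ndimage.convolve(skel.astype(np.uint8), _EIGHT, mode="constant") - skel
    degree = np.where(skel, neigh, 0).astype(np.uint8)
    return Skeleton(skeleton_mask=skel, branch_degree=degree)


def segment_labels(vessel_mask: np.ndarray) -> np.ndarray:
    """Partition a vessel mask into per-segment integer labels (0 = background).

    The skeleton is split at its branch points (degree >= 3); each remaining
    skeleton component is one segment, and every vessel pixel adopts the
    label of its nearest skeleton pixel.
    """
    vessel_mask = np.asarray(vessel_mask).astype(bool)
    skel = skeletonize(vessel_mask)
    branches = skel.skeleton_mask & (skel.branch_degree < 3)
    labels, n = ndimage.label(branches, structure=_EIGHT)
    if n == 0:
        # mask so small the whole skeleton is branch points (or empty):
        # treat every mask component as one segment
        labels, _ = ndimage.label(vessel_mask, structure=_EIGHT)
        return labels
    # propagate branch labels to all vessel pixels via nearest labelled pixel
    _, (ir, ic) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    out = labels[ir, ic]
    out[~vessel_mask] = 0
    return out


def refine_av_labels(scene: VesselScene) -> VesselScene:
    """Homogenize A/V labels per vessel segment, clipped to the vessel mask.

    Each segment takes the majority label among its original nonzero A/V
    labels; an exact tie or a segment with no labels at all becomes 0
    (unknown).  Idempotent, and never alters the vessel mask.
    """
    if not scene.vessel_mask.any():
        raise ValueError("cannot refine an empty vessel mask")
    av = scene.av_map.copy()
    av[~scene.vessel_mask] = AV_BACKGROUND
    segs = segment_labels(scene.vessel_mask)
    n = segs.max()
    refined = np.zeros_like(av)
    artery_counts = ndimage.sum_labels(av == AV_ARTERY, segs, index=np.arange(1, n + 1))
    vein_counts = ndimage.sum_labels(av == AV_VEIN, segs, index=np.arange(1, n + 1))
    winner = np.zeros(n + 1, dtype=np.uint8)
    winner[1:][artery_counts > vein_counts] = AV_ARTERY
    winner[1:][vein_counts > artery_counts] = AV_VEIN
    refined = winner[segs]
    refined[~scene.vessel_mask] = AV_BACKGROUND
    return VesselScene(
        fundus=scene.fundus,
        vessel_mask=scene.vessel_mask,
        av_map=refined,
        cup_mask=scene.cup_mask,
        subject_id=scene.subject_id,
        image_id=scene.image_id,
    )
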