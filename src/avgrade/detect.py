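"""Arterio-venous crossing candidate detection and patch extraction.

Detection works on a refined scene (A/V labels clipped to the vessel mask):

1. *contact pixels* — artery pixels with at least one vein pixel among their
   8-neighbours — are clustered by 8-connectivity into raw candidates whose
   score is the cluster size;
2. a *skeleton traversal check* keeps only candidates where both the artery
   and the vein skeleton traverse a disc around the candidate (each skeleton
   meets the disc boundary in at least two places), discarding T-junction
   contacts where one vessel merely terminates on the other;
3. nearby candidates are merged to their score-weighted centroid;
4. candidates inside the optic-cup zone are dropped — segmentation is
   unreliable there.

The artery-over-vein z-order is deliberately *not* decided geometrically:
that judgement is appearance-based and left to the learned validity
classifier downstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .prep import skeletonize
from .scene import AV_ARTERY, AV_VEIN, GRADES, VesselScene

_EIGHT = np.ones((3, 3), dtype=int)


@dataclasses.dataclass
class CrossingCandidate:
    """A detected artery-vein contact point."""

    xy: tuple[float, float]  # (row, col)
    score: float  # contact-pixel count (conserved under merging)
    in_cup: bool = False
    subject_id: str = "subject-0"
    image_id: str = "scene-0"


@dataclasses.dataclass
class LabeledPatch:
    """A 150x150 RGB crop centered on a crossing, the unit of classification."""

    pixels: np.ndarray  # (size, size, 3) uint8
    center_xy: tuple[int, int]
    is_valid: bool | None = None
    grade: str | None = None

    def __post_init__(self) -> None:
        if self.grade is not None:
            if self.grade not in GRADES:
                raise ValueError(f"unknown grade {self.grade!r}")
            if self.is_valid is False:
                raise ValueError("a graded patch must be a valid crossing")


def _boundary_crossings(skel: np.ndarray, center: tuple[float, float], radius: float) -> int:
    """Count connected skeleton clusters on a thin ring around ``center``."""
    h, w = skel.shape
    r0 = max(int(np.floor(center[0] - radius - 2)), 0)
    r1 = min(int(np.ceil(center[0] + radius + 2)) + 1, h)
    c0 = max(int(np.floor(center[1] - radius - 2)), 0)
    c1 = min(int(np.ceil(center[1] + radius + 2)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return 0
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(yy - center[0], xx - center[1])
    ring = (np.abs(d - radius) <= 1.0) & skel[r0:r1, c0:c1]
    _, n = ndimage.label(ring, structure=_EIGHT)
    return int(n)


def detect_candidates(
    scene: VesselScene,
    merge_radius_px: float = 20.0,
    check_radius_px: float = 15.0,
) -> list[CrossingCandidate]:
    """Detect crossing candidates on a refined scene.

    Raises if the scene is unrefined (A/V labels outside the vessel mask),
    since contact pixels would then reflect classifier noise rather than
    vessel geometry.
    """
    if not scene.is_refined():
        raise ValueError(
            "scene is not refined: av_map has labels outside vessel_mask; "
            "run refine_av_labels first"
        )
    artery = scene.av_map == AV_ARTERY
    vein = scene.av_map == AV_VEIN
    contact = artery & ndimage.binary_dilation(vein, structure=_EIGHT)
    labels, n = ndimage.label(contact, structure=_EIGHT)
    if n == 0:
        return []
    centroids = ndimage.center_of_mass(contact, labels, index=np.arange(1, n + 1))
    sizes = ndimage.sum_labels(contact, labels, index=np.arange(1, n + 1))

    artery_skel = skeletonize(artery).skeleton_mask
    vein_skel = skeletonize(vein).skeleton_mask

    kept: list[tuple[np.ndarray, float]] = []
    for (cy, cx), size in zip(centroids, sizes):
        if (
            _boundary_crossings(artery_skel, (cy, cx), check_radius_px) >= 2
            and _boundary_crossings(vein_skel, (cy, cx), check_radius_px) >= 2
        ):
            kept.append((np.array([cy, cx]), float(size)))
    if not kept:
        return []

    # merge candidates closer than merge_radius_px (transitively) to the
    # score-weighted centroid; total score is conserved
    pts = np.array([p for p, _ in kept])
    scores = np.array([s for _, s in kept])
    m = len(kept)
    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            if np.linalg.norm(pts[i] - pts[j]) < merge_radius_px:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)

    out: list[CrossingCandidate] = []
    for idx in groups.values():
        wsum = scores[idx].sum()
        centroid = (pts[idx] * scores[idx][:, None]).sum(axis=0) / wsum
        in_cup = False
        if scene.cup_mask is not None:
            r, c = int(round(centroid[0])), int(round(centroid[1]))
            r = np.clip(r, 0, scene.shape[0] - 1)
            c = np.clip(c, 0, scene.shape[1] - 1)
            in_cup = bool(scene.cup_mask[r, c])
        if in_cup:
            continue  # cup-zone candidates are never emitted downstream
        out.append(
            CrossingCandidate(
                xy=(float(centroid[0]), float(centroid[1])),
                score=float(wsum),
                in_cup=False,
                subject_id=scene.subject_id,
                image_id=scene.image_id,
            )
        )
    out.sort(key=lambda cand: cand.xy)
    return out


def extract_patch(scene: VesselScene, xy: tuple[int, int], size_px: int = 150) -> LabeledPatch:
    """Cut a ``size_px`` square fundus crop centered at ``xy``.

    The crop covers rows ``[r - size//2, r - size//2 + size)`` (half-open,
    0-based); windows extending past the image are reflect-padded so the
    output is always exactly ``size_px`` square.
    """
    if size_px < 1:
        raise ValueError("size_px must be >= 1")
    h, w = scene.shape
    r, c = int(xy[0]), int(xy[1])
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"xy {xy} outside a {h}x{w} image")
    half = size_px // 2
    pad = size_px  # generous; reflect requires pad < dim which holds for scenes >= size
    pad_r = min(pad, h - 1)
    pad_c = min(pad, w - 1)
    padded = np.pad(scene.fundus, ((pad_r, pad_r), (pad_c, pad_c), (0, 0)), mode="reflect")
    r0 = r - half + pad_r
    c0 = c - half + pad_c
    pixels = padded[r0 : r0 + size_px, c0 : c0 + size_px]
    if pixels.shape[:2] != (size_px, size_px):
        raise ValueError(f"scene {h}x{w} too small to cut a {size_px} px patch")
    return LabeledPatch(pixels=np.ascontiguousarray(pixels), center_xy=(r, c))


def match_candidates(
    candidates: list[CrossingCandidate],
    truth: list,
    tol_px: float = 5.0,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of candidates to ground-truth crossings.

    Pairs are matched in order of ascending distance; pairs within ``tol_px``
    count as true positives, unmatched candidates as false positives and
    unmatched truths as false negatives.  Returns ``(TP, FP, FN)``.
    """
    if tol_px <= 0:
        raise ValueError("tol_px must be positive")
    pairs = match_candidate_pairs(candidates, truth, tol_px)
    tp = len(pairs)
    return tp, len(candidates) - tp, len(truth) - tp


def match_candidate_pairs(
    candidates: list[CrossingCandidate],
    truth: list,
    tol_px: float = 5.0,
) -> list[tuple[int, int]]:
    """Greedy one-to-one (candidate_index, truth_index) pairs within ``tol_px``."""
    if not candidates or not truth:
        return []
    cand_xy = np.array([c.xy for c in candidates], dtype=float)
    truth_xy = np.array([t.crossing_xy for t in truth], dtype=float)
    d = np.linalg.norm(cand_xy[:, None, :] - truth_xy[None, :, :], axis=2)
    order = np.argsort(d, axis=None, kind="stable")
    used_c: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > tol_px:
            break
        if i in used_c or j in used_t:
            continue
        used_c.add(int(i))
        used_t.add(int(j))
        pairs.append((int(i), int(j)))
    return pairs


def write_candidates_csv(path: str | Path, candidates: list[CrossingCandidate]) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in candidates],
            "image_id": [c.image_id for c in candidates],
            "row": [c.xy[0] for c in candidates],
            "col": [c.xy[1] for c in candidates],
            "score": [c.score for c in candidates],
            "in_cup": [c.in_cup for c in candidates],
        }
    )
    df.to_csv(path, index=False)
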