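"""Subject-grouped train/validation/test splitting.

An examinee contributes several retinal images, and patches from one image
are near-duplicates of each other; splitting at the patch or image level
would leak subjects across sets.  Splits here are therefore assigned per
*subject*: subjects are shuffled, partitioned 8:1:1 by largest-remainder
rounding of subject counts, and every patch inherits its subject's split.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

SPLITS = ("train", "val", "test")


@dataclasses.dataclass
class SplitAssignment:
    """Subject -> split map plus the per-split patch manifests."""

    subject_to_split: dict[str, str]
    manifests: dict[str, pd.DataFrame]

    def split_of(self, subject_id: str) -> str:
        return self.subject_to_split[subject_id]


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    ratios = np.asarray(ratios, dtype=float)
    quotas = n * ratios / ratios.sum()
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # assign leftovers to the largest fractional parts (ties: earlier split)
    order = np.argsort(-(quotas - counts), kind="stable")
    for k in range(remainder):
        counts[order[k]] += 1
    return counts.tolist()


def group_split(
    manifest: pd.DataFrame,
    ratios: tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
) -> SplitAssignment:
    """Partition a patch manifest into train/val/test by subject.

    ``manifest`` needs a ``subject_id`` column.  Subject counts per split
    follow ``ratios`` under largest-remainder rounding; a fixed seed gives a
    fixed assignment.
    """
    subjects = sorted(manifest["subject_id"].unique())
    if len(subjects) < 3:
        raise ValueError(
            f"only {len(subjects)} subjects: a 3-way grouped split needs at least 3 "
            "(use fewer splits or more subjects)"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(subjects))
    counts = _largest_remainder(len(subjects), ratios)
    assignment: dict[str, str] = {}
    start = 0
    for split, k in zip(SPLITS, counts):
        for s in shuffled[start : start + k]:
            assignment[str(s)] = split
        start += k
    manifests = {
        split: manifest[manifest["subject_id"].map(assignment) == split].reset_index(drop=True)
        for split in SPLITS
    }
    return SplitAssignment(subject_to_split=assignment, manifests=manifests)
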