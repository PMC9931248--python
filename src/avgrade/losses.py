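"""Focal loss, its cross-entropy special case, and log-ratio class weights.

For a softmax output ``y`` and one-hot target ``t`` over L classes the focal
loss is

    L(y, t) = - sum_l  w_l * t_l * (1 - y_l)^gamma * log y_l

with per-class weights ``w_l`` (all ones when unweighted).  ``gamma = 0``
recovers the weighted cross-entropy exactly; larger ``gamma`` down-weights
well-classified samples so training concentrates on hard ones.

Class imbalance is handled by the sub-linear log-ratio weighting

    alpha_l = ln N_l / ln N

where ``N_l`` is the number of training samples of class ``l`` and ``N``
their total.  Unlike inverse-frequency weights this shrinks the influence of
rare classes only gently: a class holding half the samples still gets a
weight near 1, while a singleton class (``N_l = 1``) gets weight 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class LossSpec:
    """Focal-loss hyperparameters: focusing strength, class weights, log floor."""

    gamma: float = 0.0
    class_weights: np.ndarray | None = None
    probability_floor: float = 1e-7

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0.0 < self.probability_floor <= 1e-3:
            raise ValueError("probability_floor must lie in (0, 1e-3]")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if (w < 0).any() or (w > 1).any():
                raise ValueError("class weights must lie in [0, 1]")
            self.class_weights = w


@dataclasses.dataclass
class ClassWeights:
    """Per-class weights alpha_l = ln N_l / ln N from training-split counts."""

    counts: np.ndarray
    total: int
    weights: np.ndarray


def focal_loss(y: np.ndarray, t: np.ndarray, spec: LossSpec) -> float:
    """Evaluate the focal loss for one sample.

    ``y`` must be a probability vector (sums to 1 within 1e-6) and ``t`` a
    one-hot vector of the same length.  Probabilities are floored at
    ``spec.probability_floor`` before the logarithm.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError(f"shape mismatch: y {y.shape} vs t {t.shape}")
    if abs(y.sum() - 1.0) > 1e-6:
        raise ValueError(f"y must sum to 1 (got {y.sum()})")
    if not (np.isin(t, (0.0, 1.0)).all() and t.sum() == 1.0):
        raise ValueError("t must be one-hot")
    w = np.ones_like(y) if spec.class_weights is None else np.asarray(spec.class_weights)
    if w.shape != y.shape:
        raise ValueError(f"class_weights length {w.shape} does not match {y.shape}")
    yc = np.clip(y, spec.probability_floor, 1.0)
    terms = w * t * (1.0 - yc) ** spec.gamma * np.log(yc)
    return float(-terms.sum())


def cross_entropy(y: np.ndarray, t: np.ndarray, spec: LossSpec | None = None) -> float:
    """Weighted cross-entropy: the gamma = 0 case of :func:`focal_loss`."""
    spec = spec or LossSpec()
    return focal_loss(y, t, dataclasses.replace(spec, gamma=0.0))


def compute_class_weights(counts) -> ClassWeights:
    """Compute alpha_l = ln N_l / ln N from per-class sample counts.

    Every count must be at least 1 (ln 0 is undefined) and the total at
    least 2 (a single class with one sample would divide by ln 1 = 0).
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or len(counts) == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.floor(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(int)
    if (counts < 1).any():
        raise ValueError("every class count must be >= 1 (ln 0 undefined)")
    total = int(counts.sum())
    if total < 2:
        raise ValueError("total sample count must be >= 2 (ln 1 = 0)")
    weights = np.log(counts.astype(float)) / np.log(float(total))
    return ClassWeights(counts=counts, total=total, weights=weights)
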