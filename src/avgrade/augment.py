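"""Stochastic training-time augmentation pool.

Eleven operators, each applied independently with probability
``apply_prob`` (default 0.5) in a fixed order: vertical flip, horizontal
flip, crop-and-pad, scaling, translation, rotation, shearing, Gaussian
blur, additive pixel noise, additive low-frequency (field) noise, and
color (hue/saturation) modification.  The first seven perturb shape and
location, the next three imaging quality, and the last sensor color
characteristics.  Outputs keep the input's size and labels; geometric
operators use reflect border filling so no black corners appear.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor
from skimage.transform import AffineTransform, warp

from .detect import LabeledPatch

#: operator application order
OPERATORS = (
    "flip_v",
    "flip_h",
    "crop_pad",
    "scale",
    "translate",
    "rotate",
    "shear",
    "blur",
    "noise",
    "freq_noise",
    "color",
)


@dataclasses.dataclass
class AugmentationConfig:
    """Per-operator enable flags and parameter ranges.

    Ranges are uniform-draw bounds; all defaults are mild enough to keep a
    150 px patch's crossing in frame.
    """

    apply_prob: float = 0.5
    enabled: tuple[str, ...] = OPERATORS
    crop_frac_max: float = 0.1
    scale_range: tuple[float, float] = (0.8, 1.2)
    translate_frac_range: tuple[float, float] = (-0.1, 0.1)
    rotate_deg_range: tuple[float, float] = (-30.0, 30.0)
    shear_deg_range: tuple[float, float] = (-10.0, 10.0)
    blur_sigma_range: tuple[float, float] = (0.3, 1.5)
    noise_sigma_range: tuple[float, float] = (2.0, 8.0)  # 8-bit units
    freq_noise_amp_range: tuple[float, float] = (2.0, 8.0)
    hue_shift_range: tuple[float, float] = (-0.1, 0.1)
    sat_factor_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.apply_prob <= 1.0:
            raise ValueError("apply_prob must lie in [0, 1]")
        unknown = set(self.enabled) - set(OPERATORS)
        if unknown:
            raise ValueError(f"unknown operators: {sorted(unknown)}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _warp_affine(img: np.ndarray, tform: AffineTransform) -> np.ndarray:
    """Apply a centered affine transform with reflect filling."""
    h, w = img.shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    shift = AffineTransform(translation=-center)
    unshift = AffineTransform(translation=center)
    full = shift + tform + unshift
    out = warp(img.astype(np.float64), full.inverse, mode="reflect", order=1, preserve_range=True)
    return out


def _freq_noise_field(rng: np.random.Generator, shape: tuple[int, int], cutoff: float = 0.06) -> np.ndarray:
    """Unit-variance low-frequency random field via Fourier low-pass."""
    white = rng.normal(size=shape)
    f = np.fft.fft2(white)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    mask = np.hypot(fy, fx) < cutoff
    field = np.real(np.fft.ifft2(f * mask))
    sd = field.std()
    return field / sd if sd > 0 else field


def augment(
    patch: LabeledPatch,
    config: AugmentationConfig,
    draw: np.random.Generator | None = None,
    return_applied: bool = False,
):
    """Apply the operator pool to one patch.

    Each enabled operator fires independently with ``config.apply_prob``.
    ``draw`` carries the random state (defaults to a generator seeded from
    the config), so a fixed seed gives byte-identical outputs.
    """
    rng = draw if draw is not None else config.rng()
    img = patch.pixels.astype(np.float64)
    h, w = img.shape[:2]
    applied: list[str] = []
    for op in OPERATORS:
        if op not in config.enabled:
            continue
        if rng.random() >= config.apply_prob:
            continue
        applied.append(op)
        if op == "flip_v":
            img = img[::-1, :, :]
        elif op == "flip_h":
            img = img[:, ::-1, :]
        elif op == "crop_pad":
            mmax = int(round(config.crop_frac_max * min(h, w)))
            t, b, le, ri = (int(rng.integers(0, mmax + 1)) for _ in range(4))
            inner = img[t : h - b or h, le : w - ri or w]
            img = np.pad(inner, ((t, b), (le, ri), (0, 0)), mode="reflect")
        elif op == "scale":
            s = rng.uniform(*config.scale_range)
            img = _warp_affine(img, AffineTransform(scale=(s, s)))
        elif op == "translate":
            ty = rng.uniform(*config.translate_frac_range) * h
            tx = rng.uniform(*config.translate_frac_range) * w
            img = _warp_affine(img, AffineTransform(translation=(tx, ty)))
        elif op == "rotate":
            ang = np.deg2rad(rng.uniform(*config.rotate_deg_range))
            img = _warp_affine(img, AffineTransform(rotation=ang))
        elif op == "shear":
            sh = np.deg2rad(rng.uniform(*config.shear_deg_range))
            img = _warp_affine(img, AffineTransform(shear=sh))
        elif op == "blur":
            sigma = rng.uniform(*config.blur_sigma_range)
            img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
        elif op == "noise":
            sigma = rng.uniform(*config.noise_sigma_range)
            img = img + rng.normal(0.0, sigma, size=img.shape)
        elif op == "freq_noise":
            amp = rng.uniform(*config.freq_noise_amp_range)
            field = _freq_noise_field(rng, (h, w))
            img = img + amp * field[:, :, None]
        elif op == "color":
            hsv = _skcolor.rgb2hsv(np.clip(img, 0, 255) / 255.0)
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(*config.hue_shift_range)) % 1.0
            hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(*config.sat_factor_range), 0, 1)
            img = _skcolor.hsv2rgb(hsv) * 255.0
    out = LabeledPatch(
        pixels=np.clip(np.rint(img), 0, 255).astype(np.uint8),
        center_xy=patch.center_xy,
        is_valid=patch.is_valid,
        grade=patch.grade,
    )
    return (out, applied) if return_applied else out
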