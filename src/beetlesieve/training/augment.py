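"""Stochastic training-time image augmentation.

Each augmentation (gaussian blur, noise patches, rotation, flip,
brightness, contrast, zoom, shear warp, random crop) is applied
independently with the configured probability and a magnitude drawn from
its default range; the output is always resized to the target size last.
All randomness flows through the supplied generator, so a fixed seed gives
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktf
from skimage.filters import gaussian as _sk_gaussian


@dataclass
class AugmentConfig:
    prob: float = 0.8
    rotation_deg: float = 15.0
    brightness: float = 0.2
    contrast_range: tuple[float, float] = (0.8, 1.25)
    zoom_range: tuple[float, float] = (0.9, 1.1)
    warp_magnitude: float = 0.1
    crop_frac: float = 0.8  # retained area fraction >= this
    blur_sigma_max: float = 2.0
    noise_frac: float = 0.05  # max patch area as fraction of image
    flip: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob <= 1.0):
            raise ValueError("prob must lie in [0, 1]")


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    if image.shape[0] == size and image.shape[1] == size:
        return image
    return sktf.resize(
        image, (size, size), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


def apply_brightness(image: np.ndarray, delta: float) -> np.ndarray:
    return np.clip(image + delta, 0.0, 1.0)


def apply_contrast(image: np.ndarray, factor: float) -> np.ndarray:
    return np.clip((image - 0.5) * factor + 0.5, 0.0, 1.0)


def augment(
    image: np.ndarray,
    rng: np.random.Generator,
    cfg: AugmentConfig,
    out_size: int,
) -> np.ndarray:
    """Return an augmented copy of ``image`` resized to ``out_size``.

    With ``cfg.prob == 0`` this is a pixel-identical passthrough (after
    the final resize).
    """
    img = np.asarray(image, dtype=np.float64)
    p = cfg.prob

    if rng.random() < p:  # gaussian blur
        sigma = rng.uniform(0.0, cfg.blur_sigma_max)
        if sigma > 1e-3:
            img = _sk_gaussian(img, sigma=sigma, channel_axis=-1,
                               preserve_range=True)

    if rng.random() < p:  # random noise patch (<= noise_frac of the area)
        h, w = img.shape[:2]
        max_side_r = max(1, int(np.sqrt(cfg.noise_frac) * h))
        max_side_c = max(1, int(np.sqrt(cfg.noise_frac) * w))
        ph = int(rng.integers(1, max_side_r + 1))
        pw = int(rng.integers(1, max_side_c + 1))
        r = int(rng.integers(0, h - ph + 1))
        c = int(rng.integers(0, w - pw + 1))
        img = img.copy()
        img[r:r + ph, c:c + pw] = rng.uniform(0.0, 1.0, size=(ph, pw, img.shape[2]))

    if rng.random() < p:  # rotation
        angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        img = sktf.rotate(img, angle, resize=False, mode="edge", order=1,
                          preserve_range=True)

    if cfg.flip and rng.random() < p:  # flip
        axis = int(rng.integers(0, 2))
        img = np.flip(img, axis=axis).copy()

    if rng.random() < p:  # brightness
        img = apply_brightness(img, rng.uniform(-cfg.brightness, cfg.brightness))

    if rng.random() < p:  # contrast
        img = apply_contrast(img, rng.uniform(*cfg.contrast_range))

    if rng.random() < p:  # zoom / scaling
        f = rng.uniform(*cfg.zoom_range)
        h, w = img.shape[:2]
        tf = (
            sktf.AffineTransform(translation=(-w / 2, -h / 2))
            + sktf.AffineTransform(scale=(1.0 / f, 1.0 / f))
            + sktf.AffineTransform(translation=(w / 2, h / 2))
        )
        img = sktf.warp(img, tf.inverse, mode="edge", order=1,
                        preserve_range=True)

    if rng.random() < p:  # shear warp
        s = rng.uniform(-cfg.warp_magnitude, cfg.warp_magnitude)
        h, w = img.shape[:2]
        tf = (
            sktf.AffineTransform(translation=(-w / 2, -h / 2))
            + sktf.AffineTransform(shear=s)
            + sktf.AffineTransform(translation=(w / 2, h / 2))
        )
        img = sktf.warp(img, tf.inverse, mode="edge", order=1,
                        preserve_range=True)

    if rng.random() < p:  # random crop retaining >= crop_frac of the area
        h, w = img.shape[:2]
        frac = rng.uniform(cfg.crop_frac, 1.0)
        side = np.sqrt(frac)
        ch, cw = max(1, int(side * h)), max(1, int(side * w))
        r = int(rng.integers(0, h - ch + 1))
        c = int(rng.integers(0, w - cw + 1))
        img = img[r:r + ch, c:c + cw]

    return resize_image(np.clip(img, 0.0, 1.0), out_size)
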