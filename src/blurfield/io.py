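"""Grayscale image input/output for stimuli and blurred renderings.

Luminance is handled linearly throughout the pipeline; the display gamma
(2.2) is applied only at export time when requested.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["imwrite_gray", "imread_gray", "DISPLAY_GAMMA"]

DISPLAY_GAMMA = 2.2


def imwrite_gray(path, image: np.ndarray, bit_depth: int = 8,
                 gamma: float | None = None) -> None:
    """Write a [0, 1] or uint8 luminance map as 8- or 16-bit PNG/TIFF."""
    img = np.asarray(image, dtype=float)
    if img.dtype == np.uint8 or img.max() > 1.0:
        img = img / 255.0
    img = np.clip(img, 0.0, 1.0)
    if gamma is not None:
        img = img ** (1.0 / gamma)
    if bit_depth == 8:
        out = np.round(img * 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(img * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), out)


def imread_gray(path, gamma: float | None = None) -> np.ndarray:
    """Read a grayscale PNG/TIFF into a linear [0, 255] float map."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw[..., :3].mean(axis=-1)
    scale = 65535.0 if raw.dtype == np.uint16 else 255.0
    img = raw.astype(float) / scale
    if gamma is not None:
        img = img ** gamma
    return img * 255.0
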