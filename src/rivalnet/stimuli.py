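"""Monocular stimulus images: gratings, 1/f scene surrogates, IO, normalization.

A stimulus is a square grid of nonnegative intensities.  The vector view is
the row-major flattening of the pixel matrix; the simulator and the
reconstruction stage both use this fixed convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "StimulusImage",
    "make_grating",
    "make_scene_surrogate",
    "normalize_stimulus",
    "load_image",
    "save_image",
]


@dataclass
class StimulusImage:
    pixels: np.ndarray  # (side, side) nonnegative intensities

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("stimulus pixels must form a square matrix")
        if np.any(self.pixels < 0):
            raise ValueError("stimulus intensities must be nonnegative")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def n(self) -> int:
        return self.pixels.size

    @property
    def vector(self) -> np.ndarray:
        """Row-major flattening (exact inverse of ``from_vector``)."""
        return self.pixels.ravel(order="C")

    @property
    def mean_value(self) -> float:
        return float(self.pixels.mean())

    @classmethod
    def from_vector(cls, vec, side: int) -> "StimulusImage":
        vec = np.asarray(vec, dtype=float)
        if vec.size != side * side:
            raise ValueError("vector length does not match side**2")
        return cls(vec.reshape(side, side, order="C"))


def make_grating(side: int, orientation: str, period: int | None = None,
                 low: float = 0.0, high: float = 1.0) -> StimulusImage:
    """Square-wave grating with stripes of width ``period/2`` pixels.

    ``orientation='horizontal'`` yields horizontal stripes (every row is
    constant); ``'vertical'`` is its transpose.
    """
    if period is None:
        period = max(2, side // 5)
    if not (2 <= period <= side) or period % 2 != 0:
        raise ValueError("period must be an even integer in [2, side]")
    if not (0 <= low < high):
        raise ValueError("require 0 <= low < high")
    band = (np.arange(side) // (period // 2)) % 2
    col = np.where(band == 0, high, low)
    if orientation == "horizontal":
        pixels = np.tile(col[:, None], (1, side))
    elif orientation == "vertical":
        pixels = np.tile(col[None, :], (side, 1))
    else:
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    return StimulusImage(pixels)


def make_scene_surrogate(side: int, spectral_exponent: float = 2.0,
                         rng=None) -> StimulusImage:
    """Gaussian random field with isotropic power spectrum ~ f^-exponent.

    The default exponent of 2 gives the ~1/f amplitude spectrum typical of
    natural scenes, so the field is sparse in a frequency basis such as the
    2-D DCT.  The field is affinely rescaled into [0, 1].
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    if spectral_exponent < 0:
        raise ValueError("spectral_exponent must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    white = rng.standard_normal((side, side))
    spec = np.fft.fft2(white)
    fx = np.fft.fftfreq(side)
    f = np.sqrt(fx[:, None] ** 2 + fx[None, :] ** 2)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-spectral_exponent / 2.0)
    field = np.real(np.fft.ifft2(spec * amp))
    lo, hi = field.min(), field.max()
    if hi == lo:  # exponent 0 degenerate case cannot occur, but stay safe
        pixels = np.full_like(field, 0.5)
    else:
        pixels = (field - lo) / (hi - lo)
    return StimulusImage(pixels)


def normalize_stimulus(image: StimulusImage, m0: float) -> StimulusImage:
    """Rescale so the mean pixel value equals ``m0`` (shape preserved)."""
    mean = image.mean_value
    if mean <= 0:
        raise ValueError("cannot normalize an all-zero stimulus")
    return StimulusImage(image.pixels * (m0 / mean))


def save_image(image: StimulusImage, path) -> None:
    """Write as 16-bit grayscale PNG; intensities must lie in [0, 1]."""
    px = image.pixels
    if px.min() < 0 or px.max() > 1:
        raise ValueError("save_image expects intensities in [0, 1]")
    arr = np.round(px * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(path)  # uint16 -> 16-bit grayscale PNG


def load_image(path) -> StimulusImage:
    """Load a square grayscale image file; intensities scaled to [0, 1]."""
    img = Image.open(path)
    if img.mode in ("RGB", "RGBA", "P", "CMYK", "YCbCr"):
        raise ValueError(
            f"expected a grayscale image, got mode {img.mode!r}; convert to "
            "single-channel first")
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a single-channel image")
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(
            f"expected a square image, got shape {arr.shape}")
    if img.mode == "I;16" or arr.max() > 255:
        arr = arr / 65535.0
    elif img.mode == "F":
        pass
    else:
        arr = arr / 255.0
    return StimulusImage(arr)
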