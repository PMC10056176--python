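"""Local Niblack thresholding of grayscale biofilm images.

Crystal-violet-stained biofilm is dark on a lighter substrate, with low
global contrast at high coverage, so a single global threshold fails; the
Niblack rule sets a per-pixel threshold from the local window statistics:

    thr(x, y) = m(x, y) + k * S(x, y)

where m and S are the mean and (population) standard deviation of the
(2 radius + 1)^2 window centred at the pixel, and k is a small negative
weight (-0.1 or -0.2 are the usual choices; default -0.2).  Boundary
handling is reflective padding.  A plain global-Otsu baseline is provided
for contrast only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GrayImage",
    "NiblackParams",
    "ThresholdField",
    "BinaryMask",
    "select_channel",
    "niblack_field",
    "apply_threshold",
    "niblack_mask",
    "otsu_mask",
    "relative_coverage",
    "radius_sweep",
]

CHANNEL_NAMES = ("R", "G", "B")


@dataclass
class GrayImage:
    """2-D intensity field with an optional physical scale (px per mm)."""

    pixels: np.ndarray
    px_per_mm: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage needs a non-empty 2-D array")
        if not np.isfinite(self.pixels).all():
            raise ValueError("GrayImage intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class NiblackParams:
    """radius = half-width of the local window; window is (2r+1) x (2r+1)."""

    radius: int
    k: float = -0.2
    polarity: str = "dark_foreground"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if not np.isfinite(self.k):
            raise ValueError("k must be finite")
        if self.polarity not in {"dark_foreground", "bright_foreground"}:
            raise ValueError("polarity must be dark_foreground or bright_foreground")


@dataclass
class ThresholdField:
    thr: np.ndarray
    m: np.ndarray
    s: np.ndarray
    params: NiblackParams


@dataclass
class BinaryMask:
    pixels: np.ndarray

    @property
    def coverage(self) -> float:
        return float(self.pixels.mean())


def select_channel(rgb_image: np.ndarray,
                   override: str | None = None,
                   ) -> tuple[GrayImage, dict[str, float]]:
    """Pick the best-contrasted 8-bit channel of an RGB image.

    Contrast score = intensity standard deviation; ties go to the lower
    channel index (R < G < B).  ``override`` in {'r','g','b'} forces the
    choice.  A 2-D input passes through unchanged with a notice.
    """
    arr = np.asarray(rgb_image)
    if arr.ndim == 2:
        warnings.warn("grayscale input: channel selection skipped")
        return GrayImage(arr.astype(float)), {}
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    scores = {name: float(arr[..., i].astype(float).std())
              for i, name in enumerate(CHANNEL_NAMES)}
    if override is not None:
        idx = "rgb".index(override.lower())
    else:
        idx = int(np.argmax([scores[n] for n in CHANNEL_NAMES]))  # first max wins
    return GrayImage(arr[..., idx].astype(float)), scores


def _local_mean_sq(img: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    size = 2 * radius + 1
    m = ndimage.uniform_filter(img, size=size, mode="reflect")
    m2 = ndimage.uniform_filter(img * img, size=size, mode="reflect")
    return m, m2


def niblack_field(image: GrayImage | np.ndarray,
                  params: NiblackParams) -> ThresholdField:
    """Per-pixel Niblack threshold thr = m + k*S over the local window.

    S is the population standard deviation (division by the window pixel
    count), computed with reflective boundary padding; this matches the
    brute-force sliding-window definition exactly.
    """
    img = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("need a non-empty 2-D image")
    if params.radius >= max(img.shape):
        raise ValueError("radius too large for this image")
    m, m2 = _local_mean_sq(img, params.radius)
    var = np.maximum(m2 - m * m, 0.0)
    s = np.sqrt(var)
    thr = m + params.k * s
    return ThresholdField(thr=thr, m=m, s=s, params=params)


def apply_threshold(image: GrayImage | np.ndarray, field: ThresholdField,
                    polarity: str | None = None) -> BinaryMask:
    """Classify pixels against the threshold field.

    dark_foreground: foreground where pixel < thr; bright_foreground:
    foreground where pixel > thr.  Pixels equal to their threshold are
    background in both polarities.
    """
    img = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    if img.shape != field.thr.shape:
        raise ValueError("image and threshold field shapes differ")
    pol = polarity or field.params.polarity
    if pol == "dark_foreground":
        mask = img < field.thr
    elif pol == "bright_foreground":
        mask = img > field.thr
    else:
        raise ValueError(f"unknown polarity {pol!r}")
    return BinaryMask(pixels=mask)


def niblack_mask(image: GrayImage | np.ndarray, radius: int, k: float = -0.2,
                 polarity: str = "dark_foreground") -> BinaryMask:
    """One-call Niblack binarization."""
    params = NiblackParams(radius=radius, k=k, polarity=polarity)
    return apply_threshold(image, niblack_field(image, params))


def otsu_mask(image: GrayImage | np.ndarray,
              polarity: str = "dark_foreground") -> BinaryMask:
    """Global-Otsu baseline (for contrast with the local method only)."""
    from skimage.filters import threshold_otsu

    img = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    t = threshold_otsu(img)
    mask = img < t if polarity == "dark_foreground" else img > t
    return BinaryMask(pixels=mask)


def relative_coverage(area: float, reference_area: float) -> float:
    """Percent change of covered area with respect to a reference sample.

    Returns 100 * (area - reference) / reference; 0 for self-comparison.
    """
    if reference_area <= 0:
        raise ValueError("reference_area must be positive")
    return 100.0 * (area - reference_area) / reference_area


def radius_sweep(image: GrayImage | np.ndarray, radii: "list[int]",
                 k: float = -0.2, polarity: str = "dark_foreground",
                 ) -> "list[dict[str, float]]":
    """Coverage of the Niblack mask over a radius grid.

    Reports coverage per radius so the user can judge stability; never picks
    a radius silently (the best window size is image-dependent).
    """
    out = []
    for r in radii:
        cov = niblack_mask(image, radius=int(r), k=k, polarity=polarity).coverage
        out.append({"radius": int(r), "coverage": cov})
    return out
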