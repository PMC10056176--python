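"""Reading and writing the standard image formats used by the pipeline.

Input images are 8-bit grayscale or RGB PNG/TIFF; masks are written as 0/255
8-bit PNG; float fields (orientation, coherency, energy) as 32-bit TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["read_image", "write_gray_png", "write_mask_png", "write_field_tiff",
           "write_rgb_png"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as a numpy array (grayscale 2-D or RGB 3-D)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr


def write_gray_png(path: str | Path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8),
                    mode="L").save(path)


def write_rgb_png(path: str | Path, rgb: np.ndarray) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path)


def write_field_tiff(path: str | Path, field: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(field, dtype=np.float32))
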