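"""Reading and writing plain-raster images and label masks.

Images are 8-bit RGB (TIFF or PNG); label masks are single-channel
16-bit rasters.  Pyramidal whole-slide formats are out of scope: this
module handles the flat regions the rest of the toolkit operates on.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB image as (H, W, 3) uint8."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr.astype(np.uint8))


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel integer label mask as (H, W) uint16."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr.astype(np.uint16)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    mask = np.asarray(mask, dtype=np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask)
    else:
        iio.imwrite(path, mask)
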