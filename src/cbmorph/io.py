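"""Reading and writing of images (8-bit RGB TIFF/PNG, binary masks as PNG)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import InvalidInputError

__all__ = ["read_rgb", "write_rgb", "write_mask_png", "read_mask_png"]


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (TIFF or PNG/JPEG); alpha is dropped."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise InvalidInputError(
            f"{path}: expected 8-bit RGB image, got shape {arr.shape} dtype {arr.dtype}"
        )
    return arr


def write_rgb(path: str | Path, rgb: np.ndarray) -> None:
    """Write an 8-bit RGB image; format chosen by extension (.tif/.tiff/.png)."""
    path = Path(path)
    arr = np.ascontiguousarray(rgb, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr, photometric="rgb")
    else:
        Image.fromarray(arr, mode="RGB").save(path)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(Path(path))


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a 0/255 single-channel PNG back into a boolean mask."""
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    return arr > 127
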