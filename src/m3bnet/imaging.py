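"""Image I/O, preprocessing and paired augmentation.

Canonical representation: float arrays in [0, 1] in memory, 8-bit grayscale
PNG/TIFF on disk.  Preprocessing follows standard fundus practice: RGB is
reduced to the green channel, then contrast-limited adaptive histogram
equalization (CLAHE) lifts the vessel/background gap; training inputs are
square-resized (bilinear for intensities, nearest-neighbour for masks so
labels stay binary).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import exposure, transform

from .phantom import SamplePair


@dataclass
class ImageRecord:
    pixels: np.ndarray
    source_path: Path | None = None
    original_size: tuple[int, int] | None = None

    def __post_init__(self):
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("ImageRecord pixels must lie in [0, 1]")
        if self.original_size is None:
            self.original_size = self.pixels.shape[:2]


def read_image(path: str | Path) -> ImageRecord:
    arr = np.asarray(Image.open(path), dtype=np.float32)
    if arr.max() > 1:
        arr = arr / 255.0
    return ImageRecord(pixels=arr, source_path=Path(path))


def write_image(path: str | Path, image: ImageRecord | np.ndarray) -> None:
    arr = image.pixels if isinstance(image, ImageRecord) else image
    out = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(out).save(path)


def _as_array(image) -> tuple[np.ndarray, bool]:
    if isinstance(image, ImageRecord):
        return image.pixels, True
    return np.asarray(image), False


def _green_channel(arr: np.ndarray) -> np.ndarray:
    return arr[..., 1] if arr.ndim == 3 else arr


def clahe_enhance(image, clip_limit: float = 2.0, tile_grid: tuple[int, int] = (8, 8),
                  method: str = "adaptive"):
    """Contrast enhancement of a grayscale (or RGB → green channel) image.

    ``clip_limit`` uses the OpenCV-style scale (2.0 default) and is mapped to
    skimage's normalized clip limit.  ``method='global'`` falls back to plain
    histogram equalization.  Constant images are returned unchanged (nothing
    to equalize).
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    arr, wrapped = _as_array(image)
    arr = _green_channel(arr)
    if np.ptp(arr) == 0:
        out = arr.astype(np.float32)
    elif method == "global":
        out = exposure.equalize_hist(arr).astype(np.float32)
    elif method == "adaptive":
        kernel = (max(arr.shape[0] // tile_grid[0], 1), max(arr.shape[1] // tile_grid[1], 1))
        out = exposure.equalize_adapthist(
            np.clip(arr, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit / 100.0
        ).astype(np.float32)
    else:
        raise ValueError(f"unknown method {method!r}")
    if wrapped:
        return ImageRecord(out, source_path=image.source_path, original_size=image.original_size)
    return out


def resize_for_training(image, side: int, is_mask: bool = False):
    """Square resize: bilinear for intensities, nearest-neighbour for masks."""
    if side < 64:
        raise ValueError("side must be >= 64")
    arr, wrapped = _as_array(image)
    if arr.shape[:2] == (side, side):
        out = arr
    else:
        out = transform.resize(arr, (side, side), order=0 if is_mask else 1,
                               anti_aliasing=False, preserve_range=True)
        out = out.astype(arr.dtype) if is_mask else np.clip(out, 0.0, 1.0).astype(np.float32)
    if wrapped:
        return ImageRecord(out, source_path=image.source_path, original_size=image.original_size)
    return out


def resize_array(arr: np.ndarray, side: int, is_mask: bool = False) -> np.ndarray:
    """Resize helper without the >=64 training constraint (patch plumbing)."""
    if arr.shape[:2] == (side, side):
        return arr
    out = transform.resize(arr, (side, side), order=0 if is_mask else 1,
                           anti_aliasing=False, preserve_range=True)
    return out.astype(arr.dtype) if is_mask else out.astype(np.float32)


# ---------------------------------------------------------------------------
# paired augmentation
# ---------------------------------------------------------------------------

def _apply_rigid(arr: np.ndarray | None, hflip: bool, vflip: bool, k_rot: int):
    if arr is None:
        return None
    out = arr
    if hflip:
        out = out[:, ::-1]
    if vflip:
        out = out[::-1, :]
    if k_rot:
        out = np.rot90(out, k_rot)
    return np.ascontiguousarray(out)


def augment_pair(sample: SamplePair, rng_seed: int) -> SamplePair:
    """Apply one random rigid transform (flips + multiple-of-90° rotation)
    identically to every array of the pair, so modalities never desynchronize."""
    rng = np.random.default_rng(rng_seed)
    hflip = bool(rng.integers(2))
    vflip = bool(rng.integers(2))
    k_rot = int(rng.integers(4))
    return SamplePair(
        uwf=_apply_rigid(sample.uwf, hflip, vflip, k_rot),
        ffa=_apply_rigid(sample.ffa, hflip, vflip, k_rot),
        mask=_apply_rigid(sample.mask, hflip, vflip, k_rot),
        valid_mask=_apply_rigid(sample.valid_mask, hflip, vflip, k_rot),
        meta={**sample.meta, "augment": {"hflip": hflip, "vflip": vflip, "rot90": k_rot, "seed": rng_seed}},
    )
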