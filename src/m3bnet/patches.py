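"""Co-centred multi-scale patch extraction and inference tiling.

Training patches are triplets of windows with side ratio exactly 1:2:3
(small / middle / large), sharing one centre, each resized to a common input
size; windows overrunning the image are reflect-padded.  Inference tiles the
canvas with 50%-overlapping windows and stitches probability maps back by
uniform overlap averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .imaging import resize_array

Window = tuple[int, int, int, int]  # r0, r1, c0, c1 — half-open


@dataclass
class PatchTriplet:
    small: np.ndarray
    middle: np.ndarray
    large: np.ndarray
    center: tuple[int, int]
    source_windows: tuple[Window, Window, Window]
    common_side: int


def _window(center: tuple[int, int], side: int) -> Window:
    r, c = center
    r0 = r - side // 2
    c0 = c - side // 2
    return (r0, r0 + side, c0, c0 + side)


def extract_window(image: np.ndarray, window: Window) -> np.ndarray:
    """Crop a half-open window, reflect-padding any overrun."""
    h, w = image.shape[:2]
    r0, r1, c0, c1 = window
    pt, pb = max(0, -r0), max(0, r1 - h)
    pl, pr = max(0, -c0), max(0, c1 - w)
    crop = image[max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)]
    if pt or pb or pl or pr:
        crop = np.pad(crop, ((pt, pb), (pl, pr)), mode="reflect")
    return crop


def extract_triplet(image: np.ndarray, center: tuple[int, int], small_side: int,
                    common_side: int | None = None, is_mask: bool = False) -> PatchTriplet:
    """Windows of side s, 2s, 3s centred at ``center``, each resized to
    ``common_side`` (default: the small side)."""
    h, w = image.shape[:2]
    r, c = center
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"center {center} outside image of shape {(h, w)}")
    if small_side % 2:
        raise ValueError("small_side must be even")
    common = common_side or small_side
    windows = tuple(_window((r, c), k * small_side) for k in (1, 2, 3))
    crops = [extract_window(image, win) for win in windows]
    small, middle, large = (resize_array(crop, common, is_mask=is_mask) for crop in crops)
    return PatchTriplet(small=small, middle=middle, large=large,
                        center=(r, c), source_windows=windows, common_side=common)


def sample_training_centers(image_size: tuple[int, int], n: int, rng_seed: int,
                            vessel_mask: np.ndarray | None = None,
                            fg_fraction: float = 0.5) -> list[tuple[int, int]]:
    """Random patch centres; with a vessel mask, each centre is drawn from a
    vessel pixel with probability ``fg_fraction`` (foreground-biased sampling
    against the heavy class imbalance of thin vessels)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= fg_fraction <= 1.0:
        raise ValueError("fg_fraction must lie in [0, 1]")
    h, w = image_size
    rng = np.random.default_rng(rng_seed)
    if vessel_mask is None:
        rows = rng.integers(0, h, size=n)
        cols = rng.integers(0, w, size=n)
        return list(zip(rows.tolist(), cols.tolist()))
    fg = np.argwhere(vessel_mask > 0)
    centers = []
    for _ in range(n):
        if len(fg) and rng.random() < fg_fraction:
            r, c = fg[rng.integers(len(fg))]
        else:
            r, c = rng.integers(0, h), rng.integers(0, w)
        centers.append((int(r), int(c)))
    return centers


# ---------------------------------------------------------------------------
# tiling / stitching
# ---------------------------------------------------------------------------

@dataclass
class TileGrid:
    tile_origins: list[tuple[int, int]]
    tile_side: int
    stride: int
    canvas_size: tuple[int, int]
    weight_map: np.ndarray = field(repr=False, default=None)

    def to_json(self) -> str:
        return json.dumps({
            "tile_origins": self.tile_origins, "tile_side": self.tile_side,
            "stride": self.stride, "canvas_size": list(self.canvas_size),
        })


def make_tile_grid(canvas_size: tuple[int, int], tile_side: int, stride: int | None = None) -> TileGrid:
    """Origins at multiples of ``stride`` (default tile_side // 2, i.e. 50%
    overlap), with a final row/column clamped so every pixel is covered."""
    h, w = canvas_size
    if tile_side > h or tile_side > w:
        raise ValueError(f"tile_side {tile_side} exceeds canvas {canvas_size}")
    stride = stride or tile_side // 2

    def starts(extent):
        s = list(range(0, extent - tile_side + 1, stride))
        if s[-1] != extent - tile_side:
            s.append(extent - tile_side)
        return s

    origins = [(r, c) for r in starts(h) for c in starts(w)]
    weight = np.zeros((h, w), dtype=np.float64)
    for r, c in origins:
        weight[r:r + tile_side, c:c + tile_side] += 1.0
    assert (weight > 0).all()
    return TileGrid(tile_origins=origins, tile_side=tile_side, stride=stride,
                    canvas_size=(h, w), weight_map=weight)


def stitch(tile_predictions: list[np.ndarray], grid: TileGrid) -> np.ndarray:
    """Uniform overlap-averaging of per-tile probability maps."""
    if len(tile_predictions) != len(grid.tile_origins):
        raise ValueError(f"expected {len(grid.tile_origins)} tiles, got {len(tile_predictions)}")
    h, w = grid.canvas_size
    acc = np.zeros((h, w), dtype=np.float64)
    for pred, (r, c) in zip(tile_predictions, grid.tile_origins):
        if pred.shape != (grid.tile_side, grid.tile_side):
            raise ValueError(f"tile prediction shape {pred.shape} != {(grid.tile_side,) * 2}")
        acc[r:r + grid.tile_side, c:c + grid.tile_side] += pred
    return (acc / grid.weight_map).astype(np.float64)
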