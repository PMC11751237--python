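"""Selective Fusion Module (SFM): feature-space gating of the transfer branch.

The segmentation latent Z1 and the transfer latent Z2 are compared blockwise
in feature space.  Each map is reduced to its channel mean, the two reduced
maps are jointly min-max normalized to [0, 1], and for every block of a
(rows × cols) partition the Euclidean distance

    d = sqrt(sum_i (x_i - y_i)^2)

is computed over the block's n pixels.  Similarity is 1 − d / sqrt(n)
(sqrt(n) being the largest attainable distance for values in [0, 1]), and a
block is fused when similarity meets the threshold (default 0.5): there the
fused feature is the elementwise mean (Z1 + Z2)/2; elsewhere Z1 passes
through untouched.  A sampled variant compares only a random pixel subset
per block; the deterministic blockwise comparison is the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn import Tensor

Grid = tuple[int, int]


@dataclass
class SimilarityReport:
    block_grid: Grid
    distances: np.ndarray      # (rows, cols)
    similarities: np.ndarray   # (rows, cols), in [0, 1]
    fused_flags: np.ndarray    # bool (rows, cols)
    threshold: float

    @property
    def n_fused(self) -> int:
        return int(self.fused_flags.sum())

    def to_json(self) -> str:
        return json.dumps({
            "block_grid": list(self.block_grid),
            "distances": self.distances.tolist(),
            "similarities": self.similarities.tolist(),
            "fused_flags": self.fused_flags.astype(int).tolist(),
            "threshold": self.threshold,
        })


@dataclass
class FusedFeature:
    tensor: "Tensor | np.ndarray"
    provenance: "SimilarityReport | list[SimilarityReport] | None"


def euclidean_distance(x, y) -> float:
    """Plain Euclidean distance between two equal-length value lists."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 1:
        raise ValueError("vectors must have length >= 1")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def _channel_mean(z: np.ndarray) -> np.ndarray:
    if z.ndim == 3:
        return z.mean(axis=0)
    if z.ndim == 2:
        return z
    raise ValueError(f"expected (C,H,W) or (H,W), got shape {z.shape}")


def _block_edges(extent: int, blocks: int) -> np.ndarray:
    return np.linspace(0, extent, blocks + 1).astype(int)


def block_similarity(z1, z2, grid: Grid = (4, 4), threshold: float = 0.5,
                     mode: str = "block", sample_fraction: float = 0.25,
                     rng: np.random.Generator | None = None) -> SimilarityReport:
    """Blockwise similarity report between two feature maps of one sample.

    Accepts (C,H,W) or (H,W) arrays (Tensors are unwrapped).  Blocks of a
    non-dividing grid are truncated at the map edges.
    """
    a = _channel_mean(np.asarray(z1.data if isinstance(z1, Tensor) else z1, dtype=np.float64))
    b = _channel_mean(np.asarray(z2.data if isinstance(z2, Tensor) else z2, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi > lo:
        a = (a - lo) / (hi - lo)
        b = (b - lo) / (hi - lo)
    else:  # jointly constant maps are identical after normalization
        a = np.zeros_like(a)
        b = np.zeros_like(b)

    rows, cols = grid
    re = _block_edges(a.shape[0], rows)
    ce = _block_edges(a.shape[1], cols)
    dist = np.zeros((rows, cols))
    sim = np.zeros((rows, cols))
    for i in range(rows):
        for j in range(cols):
            xa = a[re[i]:re[i + 1], ce[j]:ce[j + 1]].ravel()
            xb = b[re[i]:re[i + 1], ce[j]:ce[j + 1]].ravel()
            if mode == "sampled":
                if rng is None:
                    raise ValueError("sampled mode needs an rng")
                k = max(1, int(round(sample_fraction * xa.size)))
                idx = rng.choice(xa.size, size=k, replace=False)
                xa, xb = xa[idx], xb[idx]
            elif mode != "block":
                raise ValueError(f"unknown similarity mode {mode!r}")
            d = euclidean_distance(xa, xb)
            dist[i, j] = d
            sim[i, j] = 1.0 - d / np.sqrt(xa.size)
    return SimilarityReport(block_grid=grid, distances=dist, similarities=sim,
                            fused_flags=sim >= threshold, threshold=threshold)


def _fusion_mask(report: SimilarityReport, shape_hw: tuple[int, int]) -> np.ndarray:
    """Expand per-block flags to a per-pixel {0,1} map."""
    rows, cols = report.block_grid
    re = _block_edges(shape_hw[0], rows)
    ce = _block_edges(shape_hw[1], cols)
    m = np.zeros(shape_hw, dtype=np.float32)
    for i in range(rows):
        for j in range(cols):
            if report.fused_flags[i, j]:
                m[re[i]:re[i + 1], ce[j]:ce[j + 1]] = 1.0
    return m


def select_and_fuse(z1, z2, threshold: float = 0.5, grid: Grid = (4, 4),
                    mode: str = "block", sample_fraction: float = 0.25,
                    rng_seed: int | None = None, op: str = "mean") -> FusedFeature:
    """Fuse Z2 into Z1 on blocks whose similarity meets the threshold.

    Flagged blocks get the elementwise mean (Z1+Z2)/2 (``op='sum'`` uses
    Z1+Z2 instead), others keep Z1 exactly.  ``z2=None`` or ``mode='off'``
    bypasses fusion wholesale.  A learned merge is available at model level
    by training the Z2 channel projection feeding this gate.  Works on
    single (C,H,W)/(H,W) arrays, batched (B,C,H,W) arrays, or autograd
    Tensors (the gate itself is non-differentiable; gradients flow through
    the fused combination).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if op not in ("mean", "sum"):
        raise ValueError(f"unknown fusion op {op!r}")
    if z2 is None or mode == "off":
        return FusedFeature(tensor=z1, provenance=None)

    is_tensor = isinstance(z1, Tensor)
    a = z1.data if is_tensor else np.asarray(z1)
    b = z2.data if isinstance(z2, Tensor) else np.asarray(z2)
    if a.shape != b.shape:
        raise ValueError(f"z1/z2 shape mismatch: {a.shape} vs {b.shape}")
    rng = np.random.default_rng(rng_seed) if mode == "sampled" else None

    batched = a.ndim == 4
    samples = range(a.shape[0]) if batched else [None]
    reports = []
    masks = []
    for s in samples:
        za, zb = (a[s], b[s]) if batched else (a, b)
        rep = block_similarity(za, zb, grid=grid, threshold=threshold,
                               mode=mode, sample_fraction=sample_fraction, rng=rng)
        reports.append(rep)
        masks.append(_fusion_mask(rep, za.shape[-2:]))
    if batched:
        gate = np.stack(masks)[:, None]           # (B,1,H,W)
    else:
        gate = masks[0] if a.ndim == 2 else masks[0][None]  # broadcast over channels

    scale = 0.5 if op == "mean" else 1.0
    if is_tensor:
        g = Tensor(gate.astype(a.dtype))
        z2t = z2 if isinstance(z2, Tensor) else Tensor(b.astype(a.dtype))
        fused = z1 * (1.0 - g) + (z1 + z2t) * (scale * g)
    else:
        fused = a * (1.0 - gate) + scale * (a + b) * gate
    prov = reports if batched else reports[0]
    return FusedFeature(tensor=fused, provenance=prov)
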