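"""Shared latent-feature container for the two branches."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor


@dataclass
class FeatureMap:
    """A latent activation map with its provenance.

    tensor: NCHW activations (autograd Tensor); stride: downsampling factor
    relative to the input patch; tag: producing branch ("Z1" segmentation /
    "Z2" transfer / intermediate names).
    """

    tensor: Tensor
    stride: int
    tag: str = ""

    def __post_init__(self):
        if not isinstance(self.tensor, Tensor):
            arr = np.asarray(self.tensor, dtype=np.float32)
            if arr.ndim == 3:
                arr = arr[None]
            self.tensor = Tensor(arr)
        if not np.isfinite(self.tensor.data).all():
            raise FloatingPointError(f"non-finite values in feature map {self.tag!r}")

    @property
    def shape(self):
        return self.tensor.data.shape
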