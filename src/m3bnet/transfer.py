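"""UWF→FFA style-transfer branch (CycleGAN lineage).

Two resnet-style generators (UWF→FFA and FFA→UWF) and two patch
discriminators, trained with a least-squares adversarial loss plus
cycle-consistency L1; because the training pairs here are pixel-aligned, a
paired L1 between the generated and the true angiogram is added on top, and
an identity L1 is available.  The UWF→FFA generator's encoder output (after
the residual blocks, at stride 4) is the latent map Z2 consumed by the
selective fusion module.

Images enter in [0, 1] and are mapped to [-1, 1] internally (tanh output);
all losses are computed in the [-1, 1] domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .segtypes import FeatureMap


@dataclass
class TransferLossWeights:
    lambda_adv: float = 1.0
    lambda_cyc: float = 10.0
    lambda_pair: float = 10.0
    lambda_id: float = 5.0


class ResidualBlock(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(channels, channels, 3, rng)
        self.norm1 = nn.InstanceNorm2d(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng)
        self.norm2 = nn.InstanceNorm2d(channels)

    def forward(self, x):
        y = self.norm1(self.conv1(x)).relu()
        y = self.norm2(self.conv2(y))
        return (x + y).relu()


class TransferGenerator(nn.Module):
    """conv7 stem → two stride-2 downsamplings → residual blocks (encoder),
    then two bilinear-upsample+conv stages → conv7 → tanh (decoder)."""

    STRIDE = 4

    def __init__(self, rng: np.random.Generator, base: int = 8, n_res: int = 2):
        b = base
        self.stem = nn.Sequential(nn.Conv2d(1, b, 7, rng), nn.InstanceNorm2d(b), nn.ReLU())
        self.down1 = nn.Sequential(nn.Conv2d(b, 2 * b, 3, rng, stride=2, padding=1),
                                   nn.InstanceNorm2d(2 * b), nn.ReLU())
        self.down2 = nn.Sequential(nn.Conv2d(2 * b, 4 * b, 3, rng, stride=2, padding=1),
                                   nn.InstanceNorm2d(4 * b), nn.ReLU())
        self.res_blocks = [ResidualBlock(4 * b, rng) for _ in range(n_res)]
        self.up1 = nn.Sequential(nn.Conv2d(4 * b, 2 * b, 3, rng), nn.InstanceNorm2d(2 * b), nn.ReLU())
        self.up2 = nn.Sequential(nn.Conv2d(2 * b, b, 3, rng), nn.InstanceNorm2d(b), nn.ReLU())
        self.head = nn.Conv2d(b, 1, 7, rng)
        self.latent_channels = 4 * b

    def encode(self, x: nn.Tensor) -> nn.Tensor:
        z = self.down2(self.down1(self.stem(x)))
        for block in self.res_blocks:
            z = block(z)
        return z

    def decode(self, z: nn.Tensor) -> nn.Tensor:
        y = self.up1(F.upsample2x(z))
        y = self.up2(F.upsample2x(y))
        return self.head(y).tanh()

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.decode(self.encode(x))


class PatchDiscriminator(nn.Module):
    """Three stride-2 conv stages → 1-channel patch logits (LSGAN)."""

    def __init__(self, rng: np.random.Generator, base: int = 8):
        b = base
        self.net = nn.Sequential(
            nn.Conv2d(1, b, 3, rng, stride=2, padding=1), nn.LeakyReLU(0.2),
            nn.Conv2d(b, 2 * b, 3, rng, stride=2, padding=1), nn.InstanceNorm2d(2 * b), nn.LeakyReLU(0.2),
            nn.Conv2d(2 * b, 4 * b, 3, rng, stride=2, padding=1), nn.InstanceNorm2d(4 * b), nn.LeakyReLU(0.2),
            nn.Conv2d(4 * b, 1, 3, rng),
        )

    def forward(self, x):
        return self.net(x)


@dataclass
class TransferPreset:
    base: int
    n_res: int
    disc_base: int


TRANSFER_PRESETS = {
    "tiny": TransferPreset(base=8, n_res=2, disc_base=8),
    "full": TransferPreset(base=64, n_res=9, disc_base=64),
}


class TransferNets(nn.Module):
    """The four style-transfer networks plus their loss weights."""

    def __init__(self, rng: np.random.Generator | int, preset: str = "tiny",
                 weights: TransferLossWeights | None = None):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        p = TRANSFER_PRESETS[preset]
        self.preset = preset
        self.g_uwf2ffa = TransferGenerator(rng, base=p.base, n_res=p.n_res)
        self.g_ffa2uwf = TransferGenerator(rng, base=p.base, n_res=p.n_res)
        self.d_ffa = PatchDiscriminator(rng, base=p.disc_base)
        self.d_uwf = PatchDiscriminator(rng, base=p.disc_base)
        self.weights = weights or TransferLossWeights()

    def generator_parameters(self):
        return self.g_uwf2ffa.parameters() + self.g_ffa2uwf.parameters()

    def discriminator_parameters(self):
        return self.d_ffa.parameters() + self.d_uwf.parameters()


def _to_tensor_pm1(patch) -> nn.Tensor:
    """[0,1] array (H,W) or (B,1,H,W) → [-1,1] NCHW Tensor."""
    if isinstance(patch, nn.Tensor):
        return patch
    arr = np.asarray(patch, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    return nn.Tensor(arr * 2.0 - 1.0)


def translate(nets: TransferNets, uwf_patch) -> tuple[np.ndarray, FeatureMap]:
    """Map a UWF patch to an FFA-like patch; also return the encoder latent Z2.

    Inference-only (no graph); training uses the generators directly.
    Returns ``ffa_hat`` in [0, 1] with the input's spatial layout.
    """
    x = _to_tensor_pm1(uwf_patch)
    h, w = x.data.shape[2], x.data.shape[3]
    s = TransferGenerator.STRIDE
    if h % s or w % s:
        raise ValueError(f"patch size {h}x{w} must be divisible by the encoder stride {s}")
    with nn.no_grad():
        z = nets.g_uwf2ffa.encode(x)
        y = nets.g_uwf2ffa.decode(z)
    ffa_hat = (y.data + 1.0) / 2.0
    squeeze = not isinstance(uwf_patch, nn.Tensor) and np.asarray(uwf_patch).ndim == 2
    if squeeze:
        ffa_hat = ffa_hat[0, 0]
    return ffa_hat, FeatureMap(tensor=z, stride=s, tag="Z2")


def encode_z2(nets: TransferNets, uwf_patch, frozen: bool = True) -> FeatureMap:
    """Encoder-only pass producing Z2 (frozen ⇒ no autograd graph)."""
    x = _to_tensor_pm1(uwf_patch)
    if frozen:
        with nn.no_grad():
            z = nets.g_uwf2ffa.encode(x)
    else:
        z = nets.g_uwf2ffa.encode(x)
    return FeatureMap(tensor=z, stride=TransferGenerator.STRIDE, tag="Z2")


def _mse_to(pred: nn.Tensor, value: float) -> nn.Tensor:
    return ((pred - value) ** 2.0).mean()


def transfer_losses(nets: TransferNets, uwf, ffa=None,
                    weights: TransferLossWeights | None = None) -> dict[str, nn.Tensor]:
    """Generator-side losses on a batch of aligned patches.

    adversarial (least-squares, both directions) + cycle L1 (both directions)
    + paired L1 (ffa_hat vs true ffa) + identity L1;
    total = adv + λ_cyc·cyc + λ_pair·pair + λ_id·id.
    """
    w = weights or nets.weights
    if ffa is None and w.lambda_pair > 0:
        raise ValueError("paired loss requested (lambda_pair > 0) but the batch is unpaired")
    x = _to_tensor_pm1(uwf)
    y = _to_tensor_pm1(ffa) if ffa is not None else None

    fake_ffa = nets.g_uwf2ffa(x)
    adv = _mse_to(nets.d_ffa(fake_ffa), 1.0)
    cyc = F.l1_loss(nets.g_ffa2uwf(fake_ffa), x)
    losses: dict[str, nn.Tensor] = {}
    if y is not None:
        fake_uwf = nets.g_ffa2uwf(y)
        adv = adv + _mse_to(nets.d_uwf(fake_uwf), 1.0)
        cyc = cyc + F.l1_loss(nets.g_uwf2ffa(fake_uwf), y)
        losses["pair"] = F.l1_loss(fake_ffa, y)
        if w.lambda_id > 0:
            losses["identity"] = F.l1_loss(nets.g_uwf2ffa(y), y) + F.l1_loss(nets.g_ffa2uwf(x), x)
    losses["adversarial"] = adv
    losses["cycle"] = cyc
    total = w.lambda_adv * adv + w.lambda_cyc * cyc
    if "pair" in losses:
        total = total + w.lambda_pair * losses["pair"]
    if "identity" in losses:
        total = total + w.lambda_id * losses["identity"]
    losses["total"] = total
    return losses


def discriminator_losses(nets: TransferNets, uwf, ffa) -> dict[str, nn.Tensor]:
    """LSGAN discriminator losses with detached fakes."""
    x = _to_tensor_pm1(uwf)
    y = _to_tensor_pm1(ffa)
    with nn.no_grad():
        fake_ffa = nets.g_uwf2ffa(x)
        fake_uwf = nets.g_ffa2uwf(y)
    d_ffa = 0.5 * (_mse_to(nets.d_ffa(y), 1.0) + _mse_to(nets.d_ffa(fake_ffa.detach()), 0.0))
    d_uwf = 0.5 * (_mse_to(nets.d_uwf(x), 1.0) + _mse_to(nets.d_uwf(fake_uwf.detach()), 0.0))
    return {"d_ffa": d_ffa, "d_uwf": d_uwf, "total": d_ffa + d_uwf}
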