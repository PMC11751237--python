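"""Segmentation branch: multi-scale encoders, LPFM, AUM decoder, refiner.

Three ResNet-style feature extractors (one per patch scale, output stride 8,
shared channel count) feed the Local Perception Fusion Module, which injects
context from the co-centred 2× and 3× windows into the small-patch features
via scaled-dot-product cross-attention:

    Gm = Att(Fm → Fs),  Gl = Att(Fl → Fs)            (context queries,
    Z1 = Fs + αm·IN(Gm) + αl·IN(Gl)                   small-patch values)

with learnable scalars αm, αl (init 0.5) and non-affine instance
normalization as the regularizer (zero-variance channels normalize to 0).

The decoder chains Attention-guided Upsampling Modules.  Each AUM doubles
resolution (bilinear, applied to its input first) and computes, with 7×7
convolutions C1..C3 on the primary/secondary paths of stage E1 and smaller
convolutions C4, C5 in stage E2:

    A1      = Att(C2C1(M), C2C1(M), C3(M))
    Output* = C2C1(M) + A1
    A2      = Att(C5(Output*), C5(Output*), C4C1(M))
    Output  = C5(Output*) + A2

A compact 2-level U-shaped refiner turns decoder features into 1-channel
logits; the map probability is their sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .fusion import FusedFeature, select_and_fuse
from .nn import functional as F
from .patches import PatchTriplet
from .segtypes import FeatureMap


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

class BasicBlock(nn.Module):
    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, stride=stride, padding=1)
        self.norm1 = nn.InstanceNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.norm2 = nn.InstanceNorm2d(cout)
        self.proj = nn.Conv2d(cin, cout, 1, rng, stride=stride, padding=0, bias=False) \
            if (cin != cout or stride != 1) else None

    def forward(self, x):
        y = self.norm1(self.conv1(x)).relu()
        y = self.norm2(self.conv2(y))
        skip = self.proj(x) if self.proj is not None else x
        return (skip + y).relu()


class ScaleEncoder(nn.Module):
    """Stem + three stages, output stride 8."""

    STRIDE = 8

    def __init__(self, rng: np.random.Generator, base: int = 8, cout: int = 16):
        self.stem = nn.Sequential(nn.Conv2d(1, base, 3, rng, stride=2, padding=1),
                                  nn.InstanceNorm2d(base), nn.ReLU())
        self.stage1 = BasicBlock(base, base, 1, rng)
        self.stage2 = BasicBlock(base, 2 * base, 2, rng)
        self.stage3 = BasicBlock(2 * base, cout, 2, rng)
        self.channels = cout

    def forward(self, x):
        return self.stage3(self.stage2(self.stage1(self.stem(x))))


class EncoderBank(nn.Module):
    """Small/middle/large extractors with one shared output contract."""

    def __init__(self, rng: np.random.Generator | int, base: int = 8, cout: int = 16):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.small = ScaleEncoder(rng, base, cout)
        self.middle = ScaleEncoder(rng, base, cout)
        self.large = ScaleEncoder(rng, base, cout)
        self.channels = cout
        self.stride = ScaleEncoder.STRIDE


def _patch_tensor(arr) -> nn.Tensor:
    if isinstance(arr, nn.Tensor):
        return arr
    a = np.asarray(arr, dtype=np.float32)
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:
        a = a[:, None]
    return nn.Tensor(a)


def encode_multiscale(triplet, bank: EncoderBank,
                      frozen_context: bool = False) -> tuple[FeatureMap, FeatureMap, FeatureMap]:
    """Run the three extractors on the (already common-size) triplet members.

    ``triplet`` may be a PatchTriplet or a (small, middle, large) sequence of
    batched arrays/Tensors.  With ``frozen_context`` the middle/large passes
    build no graph (their extractors are fixed after pre-training).
    """
    if isinstance(triplet, PatchTriplet):
        members = (triplet.small, triplet.middle, triplet.large)
    else:
        members = tuple(triplet)
    xs, xm, xl = (_patch_tensor(m) for m in members)
    if not (xs.data.shape == xm.data.shape == xl.data.shape):
        raise ValueError("triplet members must share one shape after the common resize")
    fs = bank.small(xs)
    if frozen_context:
        with nn.no_grad():
            fm = bank.middle(xm)
            fl = bank.large(xl)
    else:
        fm = bank.middle(xm)
        fl = bank.large(xl)
    shapes = {fs.data.shape, fm.data.shape, fl.data.shape}
    if len(shapes) != 1:
        raise ValueError(f"extractor outputs disagree in shape: {shapes}")
    s = bank.stride
    return (FeatureMap(fs, s, "Fs"), FeatureMap(fm, s, "Fm"), FeatureMap(fl, s, "Fl"))


# ---------------------------------------------------------------------------
# LPFM
# ---------------------------------------------------------------------------

def cross_scale_attention(query_ctx: FeatureMap, value_small: FeatureMap,
                          max_tokens: int = 1024, return_weights: bool = False):
    """Context tokens query the small-patch tokens (keys = values = small)."""
    if query_ctx.shape != value_small.shape:
        raise ValueError(f"shape mismatch {query_ctx.shape} vs {value_small.shape}")
    if query_ctx.stride != value_small.stride:
        raise ValueError("strides must match before cross-scale attention")
    out = F.scaled_dot_attention(query_ctx.tensor, value_small.tensor, value_small.tensor,
                                 max_tokens=max_tokens, return_weights=return_weights)
    if return_weights:
        attended, A = out
        return FeatureMap(attended, query_ctx.stride, f"att({query_ctx.tag})"), A
    return FeatureMap(out, query_ctx.stride, f"att({query_ctx.tag})")


def lpfm_fuse(Fs: FeatureMap, Fm: FeatureMap, Fl: FeatureMap,
              alpha_m=0.5, alpha_l=0.5, small_as_query: bool = False,
              max_tokens: int = 1024) -> FeatureMap:
    """Z1 = Fs + αm·IN(Att(Fm→Fs)) + αl·IN(Att(Fl→Fs)).

    ``small_as_query=True`` swaps the role assignment (small queries, context
    values) for the alternative reading of the attention direction.
    """
    if small_as_query:
        gm = cross_scale_attention(Fs, Fm, max_tokens)
        gl = cross_scale_attention(Fs, Fl, max_tokens)
    else:
        gm = cross_scale_attention(Fm, Fs, max_tokens)
        gl = cross_scale_attention(Fl, Fs, max_tokens)
    nm = F.instance_norm(gm.tensor)
    nl = F.instance_norm(gl.tensor)
    z1 = Fs.tensor + nn.as_tensor(alpha_m) * nm + nn.as_tensor(alpha_l) * nl
    return FeatureMap(z1, Fs.stride, "Z1")


class LPFM(nn.Module):
    """Learnable-weight wrapper around :func:`lpfm_fuse` (αm, αl init 0.5)."""

    def __init__(self, small_as_query: bool = False, max_tokens: int = 1024):
        self.alpha_m = nn.Parameter(np.float32(0.5))
        self.alpha_l = nn.Parameter(np.float32(0.5))
        self.small_as_query = small_as_query
        self.max_tokens = max_tokens

    def forward(self, Fs, Fm, Fl) -> FeatureMap:
        return lpfm_fuse(Fs, Fm, Fl, alpha_m=self.alpha_m, alpha_l=self.alpha_l,
                         small_as_query=self.small_as_query, max_tokens=self.max_tokens)


# ---------------------------------------------------------------------------
# AUM decoder
# ---------------------------------------------------------------------------

class AumBlock(nn.Module):
    """One attention-guided upsampling level (×2)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k1: int = 7, k2: int = 3, max_tokens: int = 1024):
        self.c1 = nn.Conv2d(cin, cout, k1, rng)
        self.c2 = nn.Conv2d(cout, cout, k1, rng)
        self.c3 = nn.Conv2d(cin, cout, k1, rng)
        self.c4 = nn.Conv2d(cout, cout, k2, rng)
        self.c5 = nn.Conv2d(cout, cout, k2, rng)
        self.max_tokens = max_tokens

    def forward(self, m: nn.Tensor) -> nn.Tensor:
        return aum_forward(m, self)


def aum_forward(M, block: AumBlock) -> nn.Tensor:
    """Upsample ×2, then evaluate the two attention stages literally."""
    m = M.tensor if isinstance(M, FeatureMap) else (M if isinstance(M, nn.Tensor) else nn.Tensor(np.asarray(M, dtype=np.float32)))
    if not np.isfinite(m.data).all():
        raise FloatingPointError("non-finite decoder input")
    mu = F.upsample2x(m)
    c1m = block.c1(mu)
    za = block.c2(c1m)
    zb = block.c3(mu)
    a1 = F.scaled_dot_attention(za, za, zb, max_tokens=block.max_tokens)
    out_star = za + a1
    zc = block.c5(out_star)
    zd = block.c4(c1m)
    a2 = F.scaled_dot_attention(zc, zc, zd, max_tokens=block.max_tokens)
    return zc + a2


class Refiner(nn.Module):
    """Compact 2-level U-shaped head producing 1-channel logits."""

    def __init__(self, cin: int, rng: np.random.Generator, base: int = 8):
        self.enc1 = nn.Sequential(nn.Conv2d(cin, base, 3, rng), nn.InstanceNorm2d(base), nn.ReLU())
        self.enc2 = nn.Sequential(nn.Conv2d(base, 2 * base, 3, rng, stride=2, padding=1),
                                  nn.InstanceNorm2d(2 * base), nn.ReLU())
        self.dec = nn.Sequential(nn.Conv2d(3 * base, base, 3, rng), nn.InstanceNorm2d(base), nn.ReLU())
        self.head = nn.Conv2d(base, 1, 1, rng, padding=0)

    def forward(self, x):
        e1 = self.enc1(x)
        e2 = self.enc2(e1)
        up = F.upsample2x(e2)
        return self.head(self.dec(nn.concat([e1, up], axis=1)))


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

@dataclass
class SegPreset:
    enc_base: int
    enc_channels: int
    decoder_channels: tuple[int, ...]
    refiner_base: int
    z2_channels: int          # transfer-encoder latent width to project from
    max_tokens: int = 1024


SEG_PRESETS = {
    "tiny": SegPreset(enc_base=8, enc_channels=16, decoder_channels=(8, 4, 4),
                      refiner_base=8, z2_channels=32, max_tokens=256),
    "full": SegPreset(enc_base=32, enc_channels=128, decoder_channels=(64, 32, 16),
                      refiner_base=16, z2_channels=256),
}


@dataclass
class SfmConfig:
    mode: str = "block"          # block | sampled | off
    threshold: float = 0.5
    grid: tuple[int, int] = (4, 4)
    require_z2: bool = False
    sample_fraction: float = 0.25


@dataclass
class SegOutputs:
    z1: FeatureMap
    coarse_logits: nn.Tensor
    final_logits: nn.Tensor
    probability: nn.Tensor
    fusion: FusedFeature | None = None
    captures: dict = field(default_factory=dict)


class SegModel(nn.Module):
    """Encoder bank + LPFM + Z2 projection + AUM decoder + refiner."""

    def __init__(self, rng: np.random.Generator | int, preset: str = "tiny",
                 sfm: SfmConfig | None = None, small_as_query: bool = False):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        p = SEG_PRESETS[preset]
        self.preset = preset
        self.bank = EncoderBank(rng, base=p.enc_base, cout=p.enc_channels)
        self.lpfm = LPFM(small_as_query=small_as_query, max_tokens=p.max_tokens)
        # transfer latent sits at stride 4: pool ×2 to stride 8, then project channels
        self.z2_proj = nn.Conv2d(p.z2_channels, p.enc_channels, 1, rng, padding=0)
        blocks = []
        norms = []
        cin = p.enc_channels
        for cout in p.decoder_channels:
            blocks.append(AumBlock(cin, cout, rng, max_tokens=p.max_tokens))
            norms.append(nn.InstanceNorm2d(cout))
            cin = cout
        self.decoder = blocks
        self.decoder_norms = norms  # inter-level conditioning, outside the AUM equations
        self.coarse_head = nn.Conv2d(cin, 1, 1, rng, padding=0)
        # the refiner sees the decoder features plus the raw small patch,
        # giving the refinement stage a full-resolution intensity pathway
        self.refiner = Refiner(cin + 1, rng, base=p.refiner_base)
        self.sfm = sfm or SfmConfig()

    # -- pieces ---------------------------------------------------------------
    def project_z2(self, z2: FeatureMap) -> FeatureMap:
        t = z2.tensor
        stride = z2.stride
        if stride * 2 == self.bank.stride:
            t = F.avg_pool2d(t, 2)
            stride *= 2
        if stride != self.bank.stride:
            raise ValueError(f"cannot align Z2 stride {z2.stride} to encoder stride {self.bank.stride}")
        return FeatureMap(self.z2_proj(t), stride, "Z2proj")

    def decode(self, m: nn.Tensor, capture: tuple = ()) -> tuple[nn.Tensor, dict]:
        captures = {}
        x = m
        last = len(self.decoder) - 1
        for i, (block, norm) in enumerate(zip(self.decoder, self.decoder_norms)):
            x = block(x)
            name = f"decoder_{i}"
            if name in capture:
                captures[name] = x
            if i < last:  # keep the final AUM output un-renormalized
                x = norm(x).relu()
        if "decoder_final" in capture:
            captures["decoder_final"] = x
        return x, captures

    # -- full forward ---------------------------------------------------------
    def forward(self, triplet, z2: FeatureMap | None = None,
                frozen_context: bool = True, capture: tuple = ()) -> SegOutputs:
        fs, fm, fl = encode_multiscale(triplet, self.bank, frozen_context=frozen_context)
        z1 = self.lpfm(fs, fm, fl)

        fusion = None
        if z2 is None:
            if self.sfm.require_z2 and self.sfm.mode != "off":
                raise ValueError("model configured to require the transfer latent Z2, none given")
            m = z1.tensor
        elif self.sfm.mode == "off":
            m = z1.tensor
        else:
            z2p = self.project_z2(z2)
            if z2p.shape != z1.shape:
                raise ValueError(f"Z1/Z2 shape mismatch after projection: {z1.shape} vs {z2p.shape}")
            fusion = select_and_fuse(z1.tensor, z2p.tensor, threshold=self.sfm.threshold,
                                     grid=self.sfm.grid, mode=self.sfm.mode,
                                     sample_fraction=self.sfm.sample_fraction)
            m = fusion.tensor

        feats, captures = self.decode(m, capture=capture)
        coarse = self.coarse_head(feats)
        small = triplet.small if isinstance(triplet, PatchTriplet) else triplet[0]
        logits = self.refiner(nn.concat([feats, _patch_tensor(small)], axis=1))
        return SegOutputs(z1=z1, coarse_logits=coarse, final_logits=logits,
                          probability=logits.sigmoid(), fusion=fusion, captures=captures)


def segment_patch(triplet, z2, model: SegModel, capture: tuple = ()) -> SegOutputs:
    """Single-patch convenience wrapper over :meth:`SegModel.forward`."""
    return model(triplet, z2=z2, capture=capture)


def build_model(seed_or_rng, preset: str = "tiny", **kwargs) -> SegModel:
    return SegModel(seed_or_rng, preset=preset, **kwargs)
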