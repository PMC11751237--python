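"""Array-level neural-net primitives with custom backward passes.

conv2d uses a shift-and-accumulate scheme (one GEMM per kernel offset) which
is considerably faster than im2col for the small channel counts used here,
and keeps memory flat.  Bilinear resizing is expressed as two separable dense
interpolation matrices, so its backward pass is just the transposed matrices.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int | None = None) -> Tensor:
    """2-D cross-correlation over NCHW input with OIHW weights, zero padding.

    ``padding=None`` means "same" for stride 1 (k//2)."""
    B, C, H, W = x.data.shape
    O, Ci, k, k2 = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Ci}")
    if k != k2:
        raise ValueError("only square kernels supported")
    p = k // 2 if padding is None else padding
    s = stride
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    xf = np.ascontiguousarray(xp.transpose(1, 0, 2, 3))  # C,B,Hp,Wp
    wd = w.data
    acc = np.zeros((O, B * Ho * Wo), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            sl = xf[:, :, i:i + s * (Ho - 1) + 1:s, j:j + s * (Wo - 1) + 1:s]
            acc += wd[:, :, i, j] @ sl.reshape(C, -1)
    out_data = acc.reshape(O, B, Ho, Wo).transpose(1, 0, 2, 3)
    if b is not None:
        out_data = out_data + b.data.reshape(1, O, 1, 1)

    def backward(grad):
        yf = np.ascontiguousarray(grad.transpose(1, 0, 2, 3)).reshape(O, -1)
        if w.requires_grad:
            dw = np.empty_like(wd)
            for i in range(k):
                for j in range(k):
                    sl = xf[:, :, i:i + s * (Ho - 1) + 1:s, j:j + s * (Wo - 1) + 1:s]
                    dw[:, :, i, j] = yf @ sl.reshape(C, -1).T
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxf = np.zeros_like(xf)
            for i in range(k):
                for j in range(k):
                    contrib = (wd[:, :, i, j].T @ yf).reshape(C, B, Ho, Wo)
                    dxf[:, :, i:i + s * (Ho - 1) + 1:s, j:j + s * (Wo - 1) + 1:s] += contrib
            dxp = dxf.transpose(1, 0, 2, 3)
            if p:
                dxp = dxp[:, :, p:-p, p:-p]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# pooling / resizing
# ---------------------------------------------------------------------------

def avg_pool2d(x: Tensor, k: int) -> Tensor:
    B, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: spatial dims {H}x{W} not divisible by {k}")
    out_data = x.data.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward(grad):
        if x.requires_grad:
            g = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
            x._accumulate(g.astype(x.data.dtype))

    return Tensor._make(out_data, (x,), backward)


def _interp_matrix(n_out: int, n_in: int, dtype=np.float32) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix, half-pixel-centre convention."""
    M = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = (src - i0).astype(dtype)
    M[np.arange(n_out), i0] += 1.0 - f
    M[np.arange(n_out), i1] += f
    return M


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of an NCHW tensor (up or down)."""
    B, C, H, W = x.data.shape
    if (out_h, out_w) == (H, W):
        return x
    Mh = _interp_matrix(out_h, H, x.data.dtype)
    Mw = _interp_matrix(out_w, W, x.data.dtype)
    t = x.data @ Mw.T                                  # B,C,H,Wo
    out_data = (t.swapaxes(2, 3) @ Mh.T).swapaxes(2, 3)  # B,C,Ho,Wo

    def backward(grad):
        if x.requires_grad:
            g = (grad.swapaxes(2, 3) @ Mh).swapaxes(2, 3)
            x._accumulate(g @ Mw)

    return Tensor._make(out_data, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    _, _, H, W = x.data.shape
    return resize_bilinear(x, 2 * H, 2 * W)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel spatial standardization (no affine).

    Constant channels normalize to exactly zero (variance 0 + eps)."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward(grad):
        if x.requires_grad:
            m = grad.mean(axis=(2, 3), keepdims=True)
            mx = (grad * xhat).mean(axis=(2, 3), keepdims=True)
            x._accumulate(inv * (grad - m - xhat * mx))

    return Tensor._make(xhat, (x,), backward)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def _pool_factor(h: int, w: int, max_tokens: int) -> int:
    f = 1
    while (h // f) * (w // f) > max_tokens:
        f *= 2
    return f


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         max_tokens: int = 1024,
                         return_weights: bool = False):
    """Scaled dot-product attention over feature-map tokens.

    q, k, v: NCHW tensors of identical shape.  Each spatial position is a
    token with C channels; A = softmax(QK'/sqrt(C)) row-normalized over keys,
    output = A V reshaped back to the map.  Maps larger than ``max_tokens``
    tokens are average-pooled before attention and the attended map is
    bilinearly resized back, bounding the N^2 cost.
    """
    if q.data.shape != k.data.shape or q.data.shape != v.data.shape:
        raise ValueError("attention expects q, k, v of identical shape")
    if not (np.isfinite(q.data).all() and np.isfinite(k.data).all() and np.isfinite(v.data).all()):
        raise FloatingPointError("non-finite values in attention inputs")
    B, C, H, W = q.data.shape
    f = _pool_factor(H, W, max_tokens)
    if f > 1:
        q, k, v = avg_pool2d(q, f), avg_pool2d(k, f), avg_pool2d(v, f)
    Hp, Wp = q.data.shape[2], q.data.shape[3]
    N = Hp * Wp

    tq = q.reshape(B, C, N).transpose(0, 2, 1)
    tk = k.reshape(B, C, N).transpose(0, 2, 1)
    tv = v.reshape(B, C, N).transpose(0, 2, 1)
    A = ((tq @ tk.transpose(0, 2, 1)) * (1.0 / np.sqrt(C))).softmax(axis=-1)
    out = (A @ tv).transpose(0, 2, 1).reshape(B, C, Hp, Wp)
    if f > 1:
        out = resize_bilinear(out, H, W)
    if return_weights:
        return out, A
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_loss(prob: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Mean binary cross-entropy on probabilities (already sigmoid-ed)."""
    t = np.asarray(target, dtype=prob.data.dtype)
    p = prob.clip(eps, 1.0 - eps)
    return -((Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log()).mean())


def soft_dice_loss(prob: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 - soft Dice overlap; eps smooths the empty-mask case."""
    t = Tensor(np.asarray(target, dtype=prob.data.dtype))
    inter = (prob * t).sum()
    denom = prob.sum() + t.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def l1_loss(a: Tensor, b) -> Tensor:
    b = as_tensor(b)
    return (a - b).abs().mean()
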