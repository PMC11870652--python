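"""Convolutional encoder mapping stimulus images to drift-rate means.

Architecture: six convolutional blocks (3x3 kernels, stride 1, same
padding; each block is conv -> ReLU -> instance normalization -> 2x2
max-pool), a fully-connected hidden layer with ReLU and dropout (rate 0.5),
and a 4-unit linear output head.  With the default widths
(64, 64, 128, 128, 128, 256, 1024) and 128x128x3 inputs the spatial size
halves per block (128 -> 64 -> 32 -> 16 -> 8 -> 4 -> 2), so the flattened
fully-connected input is 2*2*256 = 1024.  The same network serves as the
drift-rate head of the generative model and, unchanged except for the loss,
as a 4-class logits head for task-optimized training.

Everything here is plain NumPy with hand-written backpropagation: forward
passes cache the intermediates needed by :func:`backward`, which returns
gradients for every trainable array given the upstream gradient on the
4-vector outputs.  Instance normalization is per-image, per-channel over the
spatial dimensions with no learnable affine terms (epsilon 1e-5).  Weights
are LeCun-normal initialized, biases zero, reproducibly from a seed.

Also provided: the training-time augmentation pipeline (small random
translations plus a coarse elastic warp applied with probability 0.75) and
activation extraction for the representation analyses (per-channel spatial
max of the post-ReLU maps, taken before normalization; all units for the
fully-connected layer; inactive units removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import resize

__all__ = [
    "EncoderConfig",
    "ActivationMatrix",
    "init_params",
    "forward",
    "backward",
    "extract_activations",
    "augment_batch",
    "AugmentConfig",
]

_IN_EPS = 1e-5


@dataclass(frozen=True)
class EncoderConfig:
    """Encoder hyper-structure.

    ``head`` selects the semantic interpretation of the 4 outputs (``drift``
    means or class ``logits``); the computation graph is identical.  A
    reduced desk-scale variant (e.g. 32x32 inputs, widths (16, 16, 32)) is a
    first-class configuration for CPU-sized runs.
    """

    input_hw: tuple = (128, 128)
    in_channels: int = 3
    conv_channels: tuple = (64, 64, 128, 128, 128, 256)
    fc_width: int = 1024
    n_out: int = 4
    dropout: float = 0.5
    head: str = "drift"

    def __post_init__(self):
        if self.head not in ("drift", "logits"):
            raise ValueError("head must be 'drift' or 'logits'")
        h, w = self.input_hw
        for _ in self.conv_channels:
            if h % 2 or w % 2:
                raise ValueError(
                    f"spatial size must halve cleanly per block, got {self.input_hw}"
                    f" with {len(self.conv_channels)} blocks"
                )
            h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ValueError("too many conv blocks for the input size")

    @property
    def spatial_sizes(self) -> tuple:
        """Spatial side lengths entering each block, plus the final size."""
        h = self.input_hw[0]
        sizes = [h]
        for _ in self.conv_channels:
            h //= 2
            sizes.append(h)
        return tuple(sizes)

    @property
    def fc_in(self) -> int:
        h, w = self.input_hw
        f = 2 ** len(self.conv_channels)
        return (h // f) * (w // f) * self.conv_channels[-1]

    @property
    def n_layers(self) -> int:
        """Hidden layers with unit activity: the conv blocks plus the FC."""
        return len(self.conv_channels) + 1


def init_params(cfg: EncoderConfig, seed=0) -> dict:
    """LeCun-normal weights (std = 1/sqrt(fan_in)), zero biases; seeded.

    An externally trained checkpoint for the early conv layers may be
    spliced in afterwards by overwriting the corresponding arrays.
    """
    rng = np.random.default_rng(seed)
    params = {}
    c_in = cfg.in_channels
    for i, c_out in enumerate(cfg.conv_channels):
        fan_in = c_in * 9
        params[f"conv{i}_w"] = rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                                          size=(c_out, c_in, 3, 3))
        params[f"conv{i}_b"] = np.zeros(c_out)
        c_in = c_out
    params["fc_w"] = rng.normal(0.0, 1.0 / np.sqrt(cfg.fc_in),
                                size=(cfg.fc_width, cfg.fc_in))
    params["fc_b"] = np.zeros(cfg.fc_width)
    params["out_w"] = rng.normal(0.0, 1.0 / np.sqrt(cfg.fc_width),
                                 size=(cfg.n_out, cfg.fc_width))
    params["out_b"] = np.zeros(cfg.n_out)
    return params


def _conv2d(x, w, b):
    """Same-padding 3x3 correlation via shift-and-add matmuls.

    Channels-last layout: x (N,H,W,C), w (O,C,3,3) -> (N,H,W,O).  Looping
    over the 9 kernel taps keeps every inner product a plain channel
    contraction (one GEMM per tap, no im2col copy, no transposes).
    """
    n, h, wd, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    y = np.empty((n, h, wd, w.shape[0]))
    y[:] = b
    for i in range(3):
        for j in range(3):
            y += xp[:, i:i + h, j:j + wd, :] @ w[:, :, i, j].T
    return y


def _conv2d_backward(x, w, dy):
    """Gradients of _conv2d: returns (dx, dw, db)."""
    n, h, wd, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    db = dy.sum(axis=(0, 1, 2))
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for i in range(3):
        for j in range(3):
            patch = xp[:, i:i + h, j:j + wd, :]
            dw[:, :, i, j] = np.tensordot(dy, patch,
                                          axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, i:i + h, j:j + wd, :] += dy @ w[:, :, i, j]
    return dxp[:, 1:-1, 1:-1, :], dw, db


def _instance_norm(x):
    m = x.mean(axis=(1, 2), keepdims=True)
    v = x.var(axis=(1, 2), keepdims=True)
    inv = 1.0 / np.sqrt(v + _IN_EPS)
    return (x - m) * inv, inv


def _instance_norm_backward(y, inv, dy):
    """Backprop through (x - m)/sqrt(v + eps), given normalized y and 1/std."""
    s = y.shape[1] * y.shape[2]
    dy_sum = dy.sum(axis=(1, 2), keepdims=True)
    dyy_sum = (dy * y).sum(axis=(1, 2), keepdims=True)
    return inv * (dy - dy_sum / s - y * dyy_sum / s)


def _maxpool(x):
    n, h, w, c = x.shape
    x6 = x.reshape(n, h // 2, 2, w // 2, 2, c)
    y = x6.max(axis=(2, 4))
    mask = x6 == y[:, :, None, :, None, :]
    mask = mask / mask.sum(axis=(2, 4), keepdims=True)   # split ties evenly
    return y, mask


def _maxpool_backward(mask, dy):
    n, h2, _, w2, _, c = mask.shape
    d = mask * dy[:, :, None, :, None, :]
    return d.reshape(n, h2 * 2, w2 * 2, c)


def _check_images(images, cfg):
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    if images.shape[1:] != (*cfg.input_hw, cfg.in_channels):
        raise ValueError(
            f"expected images (N, {cfg.input_hw[0]}, {cfg.input_hw[1]}, "
            f"{cfg.in_channels}), got {images.shape}"
        )
    return images


def forward(images, params, cfg: EncoderConfig, mode="eval", rng=None,
            return_cache=False):
    """Run the encoder on a batch of (N, H, W, 3) images in [0, 1].

    ``mode="train"`` activates dropout (inverted scaling, needs ``rng``);
    ``mode="eval"`` is a pure deterministic function of (images, params).
    With ``return_cache`` the intermediates needed by :func:`backward` (and
    the per-layer post-ReLU maps used by activation extraction) are returned
    alongside the (N, 4) outputs.
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    if mode == "train" and rng is None:
        raise ValueError("train mode requires rng for dropout")
    x = _check_images(images, cfg)
    cache = {"inputs": x, "relu_maps": []}
    for i in range(len(cfg.conv_channels)):
        pre = _conv2d(x, params[f"conv{i}_w"], params[f"conv{i}_b"])
        relu = np.maximum(pre, 0.0)
        cache[f"conv{i}_x"] = x
        cache[f"conv{i}_relu"] = relu
        cache["relu_maps"].append(relu)
        normed, inv = _instance_norm(relu)
        cache[f"conv{i}_norm"] = normed
        cache[f"conv{i}_inv"] = inv
        x, mask = _maxpool(normed)
        cache[f"conv{i}_poolmask"] = mask
    flat = x.reshape(x.shape[0], -1)
    cache["flat"] = flat
    fc_pre = flat @ params["fc_w"].T + params["fc_b"]
    fc_relu = np.maximum(fc_pre, 0.0)
    cache["fc_relu"] = fc_relu
    if mode == "train" and cfg.dropout > 0:
        keep = rng.random(fc_relu.shape) >= cfg.dropout
        drop = keep / (1.0 - cfg.dropout)
    else:
        drop = np.ones_like(fc_relu)
    cache["dropmask"] = drop
    fc_out = fc_relu * drop
    cache["fc_out"] = fc_out
    out = fc_out @ params["out_w"].T + params["out_b"]
    if return_cache:
        return out, cache
    return out


def backward(d_out, params, cfg: EncoderConfig, cache) -> dict:
    """Backpropagate an upstream (N, 4) gradient through the encoder.

    Returns a dict of gradients keyed like ``params``.
    """
    grads = {}
    grads["out_w"] = d_out.T @ cache["fc_out"]
    grads["out_b"] = d_out.sum(axis=0)
    d_fc_out = d_out @ params["out_w"]
    d_fc_relu = d_fc_out * cache["dropmask"]
    d_fc_pre = d_fc_relu * (cache["fc_relu"] > 0)
    grads["fc_w"] = d_fc_pre.T @ cache["flat"]
    grads["fc_b"] = d_fc_pre.sum(axis=0)
    d_flat = d_fc_pre @ params["fc_w"]
    n = d_flat.shape[0]
    last = len(cfg.conv_channels) - 1
    f = 2 ** len(cfg.conv_channels)
    dx = d_flat.reshape(n, cfg.input_hw[0] // f, cfg.input_hw[1] // f,
                        cfg.conv_channels[-1])
    for i in range(last, -1, -1):
        d_norm = _maxpool_backward(cache[f"conv{i}_poolmask"], dx)
        d_relu = _instance_norm_backward(cache[f"conv{i}_norm"],
                                         cache[f"conv{i}_inv"], d_norm)
        d_pre = d_relu * (cache[f"conv{i}_relu"] > 0)
        dx, dw, db = _conv2d_backward(cache[f"conv{i}_x"],
                                      params[f"conv{i}_w"], d_pre)
        grads[f"conv{i}_w"] = dw
        grads[f"conv{i}_b"] = db
    return grads


@dataclass(frozen=True)
class ActivationMatrix:
    """N x K_l unit activations for one layer, inactive units removed.

    ``active_units`` maps each retained column back to its original channel
    (or FC unit) index.
    """

    values: np.ndarray
    layer: int
    active_units: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != self.active_units.shape[0]:
            raise ValueError("active_units must index the columns of values")


def extract_activations(images, params, cfg: EncoderConfig, layer: int,
                        batch_size=256) -> ActivationMatrix:
    """Probe unit activity at one hidden layer (eval mode).

    ``layer`` is 1..n_layers: conv blocks give the per-channel spatial max of
    the post-ReLU map (taken before instance normalization and pooling); the
    final (FC) layer gives post-ReLU unit outputs directly.  Units with no
    strictly positive response to any probe stimulus are removed; the index
    map of the surviving columns is recorded.
    """
    if not 1 <= layer <= cfg.n_layers:
        raise ValueError(f"layer must be in 1..{cfg.n_layers}")
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    chunks = []
    for lo in range(0, images.shape[0], batch_size):
        _, cache = forward(images[lo:lo + batch_size], params, cfg,
                           mode="eval", return_cache=True)
        if layer <= len(cfg.conv_channels):
            acts = cache["relu_maps"][layer - 1].max(axis=(1, 2))
        else:
            acts = cache["fc_relu"]
        chunks.append(acts)
    acts = np.concatenate(chunks, axis=0)
    active = np.flatnonzero((acts > 0).any(axis=0))
    return ActivationMatrix(acts[:, active], layer, active)


@dataclass(frozen=True)
class AugmentConfig:
    """Training-set augmentation: pixel jitter plus elastic warp.

    Horizontal shifts are drawn from U[0, ``max_dx``] and vertical shifts
    from U[0, ``max_dy``], rounded to the nearest pixel; the elastic warp
    displaces pixels by a coarse random field (node spacing ``coarseness``
    px, amplitude ``strength`` px, bilinear upsampling) and is applied to
    each image independently with probability ``warp_prob``.
    """

    max_dx: float = 2.0
    max_dy: float = 1.0
    warp_prob: float = 0.75
    warp_strength: float = 3.0
    warp_coarseness: int = 32


def _elastic_warp(img, rng, strength, coarseness):
    h, w, c = img.shape
    nodes = (max(int(np.ceil(h / coarseness)), 1) + 1,
             max(int(np.ceil(w / coarseness)), 1) + 1)
    out = np.empty_like(img)
    dy = resize(rng.normal(0.0, 1.0, nodes), (h, w), order=1) * strength
    dx = resize(rng.normal(0.0, 1.0, nodes), (h, w), order=1) * strength
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([yy + dy, xx + dx])
    for ch in range(c):
        out[:, :, ch] = map_coordinates(img[:, :, ch], coords, order=1,
                                        mode="nearest")
    return out


def augment_batch(images, seed=None, rng=None,
                  cfg: AugmentConfig = AugmentConfig()) -> np.ndarray:
    """Randomly translate and elastically warp a batch of (N, H, W, C) images.

    Deterministic given the seed/generator.  With all magnitudes zero and
    ``warp_prob = 0`` this is the identity.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    images = np.asarray(images, dtype=float)
    out = np.empty_like(images)
    for i, img in enumerate(images):
        dx = int(np.rint(rng.uniform(0.0, cfg.max_dx)))
        dy = int(np.rint(rng.uniform(0.0, cfg.max_dy)))
        shifted = img
        if dx or dy:
            shifted = np.zeros_like(img)
            h, w = img.shape[:2]
            shifted[dy:, dx:] = img[:h - dy or None, :w - dx or None]
            # fill vacated margins with the edge rows/cols (uniform background)
            if dy:
                shifted[:dy] = shifted[dy:dy + 1]
            if dx:
                shifted[:, :dx] = shifted[:, dx:dx + 1]
        if rng.random() < cfg.warp_prob:
            shifted = _elastic_warp(shifted, rng, cfg.warp_strength,
                                    cfg.warp_coarseness)
        out[i] = shifted
    return out
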