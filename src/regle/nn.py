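"""Minimal NumPy neural-network kernel for the waveform autoencoders.

Implements exactly the pieces the encoder/decoder topology needs —
same-padded 1-D convolution, max pooling, nearest-neighbour upsampling,
dense layers, ReLU and Adam — with hand-written backward passes.
Arrays are laid out (batch, length, channels) in float32; convolutions
are evaluated as a single matmul over an im2col view, which keeps
training on a desk CPU fast enough for cohort-scale experiments.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np

Array = np.ndarray
F32 = np.float32


# --------------------------------------------------------------------------
# layer primitives (forward returns output + cache for backward)
# --------------------------------------------------------------------------

def conv1d_forward(x: Array, W: Array, b: Array):
    """Same-padded 1-D convolution; W has shape (k, c_in, c_out).

    Evaluated as a sum of k shifted matmuls, which avoids im2col copies.
    """
    k = W.shape[0]
    pl = k // 2
    pr = k - 1 - pl
    B, L, c_in = x.shape
    xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
    y = np.broadcast_to(b, (B, L, W.shape[2])).copy()
    for i in range(k):
        y += xp[:, i : i + L, :] @ W[i]
    return y, (xp, W, x.shape, pl)


def conv1d_backward(dy: Array, cache):
    xp, W, xshape, pl = cache
    k, c_in, c_out = W.shape
    B, L, _ = xshape
    dW = np.empty_like(W)
    dyf = dy.reshape(B * L, c_out)
    for i in range(k):
        seg = np.ascontiguousarray(xp[:, i : i + L, :]).reshape(B * L, c_in)
        dW[i] = seg.T @ dyf
    db = dy.sum(axis=(0, 1))
    dxp = np.zeros_like(xp)
    for i in range(k):
        dxp[:, i : i + L, :] += dy @ W[i].T
    dx = dxp[:, pl : pl + L, :]
    return dx, dW, db


def maxpool_forward(x: Array, p: int):
    B, L, C = x.shape
    Lp = math.ceil(L / p)
    pad = Lp * p - L
    if pad:
        x = np.pad(x, ((0, 0), (0, pad), (0, 0)), constant_values=-np.inf)
    xr = x.reshape(B, Lp, p, C)
    y = xr.max(axis=2)
    return y, (xr, y, (B, L, C), p)


def maxpool_backward(dy: Array, cache):
    xr, y, (B, L, C), p = cache
    Lp = dy.shape[1]
    # route gradient to the argmax; exact float ties are vanishingly rare
    # and then receive the gradient jointly
    dxr = (xr == y[:, :, None, :]) * dy[:, :, None, :]
    return dxr.reshape(B, Lp * p, C)[:, :L, :]


def upsample_forward(x: Array, p: int):
    return np.repeat(x, p, axis=1), (x.shape, p)


def upsample_backward(dy: Array, cache):
    (B, L, C), p = cache
    return dy.reshape(B, L, p, C).sum(axis=2)


def dense_forward(x: Array, W: Array, b: Array):
    return x @ W + b, x


def dense_backward(dy: Array, x: Array, W: Array):
    return dy @ W.T, x.T @ dy, dy.sum(axis=0)


LEAK = np.float32(0.1)


def relu_forward(x: Array):
    """Leaky ReLU; the small negative slope prevents dead units."""
    y = np.where(x > 0, x, LEAK * x)
    return y, y


def relu_backward(dy: Array, y: Array):
    return dy * np.where(y > 0, np.float32(1.0), LEAK)


# --------------------------------------------------------------------------
# Adam
# --------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Dict[str, Array], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float = 10.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, Array], grads: Dict[str, Array]) -> None:
        if self.clip_norm is not None:
            total = math.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if total > self.clip_norm:
                scale = np.float32(self.clip_norm / total)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )


# --------------------------------------------------------------------------
# the convolutional VAE (3 conv + 3 FC mirror topology)
# --------------------------------------------------------------------------

class ConvVAE:
    """Conv encoder -> Gaussian bottleneck -> mirrored conv decoder.

    Encoder: three same-padded conv layers (each followed by max pooling
    and ReLU), flatten, three dense layers, then two linear heads for the
    posterior mean and log-variance.  Decoder: three dense layers from
    the (optionally EDF-augmented) latent, then three conv layers each
    preceded by 2x upsampling; the last conv is linear and the output is
    cropped to the input length.  ``latent_dim == 0`` degenerates to a
    deterministic decoder-only model driven purely by injected features.
    """

    def __init__(self, input_length: int, input_channels: int, latent_dim: int,
                 n_injected: int = 0, conv_channels=(8, 16, 32), kernel_size: int = 5,
                 pool_size: int = 2, fc_widths=(128, 64, 32), seed: int = 0):
        if latent_dim == 0 and n_injected == 0:
            raise ValueError("need a latent or injected input to decode from")
        self.L = input_length
        self.C = input_channels
        self.latent_dim = latent_dim
        self.n_injected = n_injected
        self.conv_channels = tuple(conv_channels)
        self.k = kernel_size
        self.p = pool_size
        self.fc_widths = tuple(fc_widths)
        rng = np.random.default_rng(seed)

        # pooled length after the three encoder stages
        Lc = input_length
        for _ in range(3):
            Lc = math.ceil(Lc / pool_size)
        self.Lc = Lc
        c1, c2, c3 = self.conv_channels
        f1, f2, f3 = self.fc_widths
        d_in = latent_dim + n_injected

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(F32)

        P: Dict[str, Array] = {}
        if latent_dim > 0:
            P["e_conv1_W"] = he((self.k, input_channels, c1), self.k * input_channels)
            P["e_conv2_W"] = he((self.k, c1, c2), self.k * c1)
            P["e_conv3_W"] = he((self.k, c2, c3), self.k * c2)
            P["e_fc1_W"] = he((Lc * c3, f1), Lc * c3)
            P["e_fc2_W"] = he((f1, f2), f1)
            P["e_fc3_W"] = he((f2, f3), f2)
            P["e_mu_W"] = he((f3, latent_dim), f3)
            P["e_lv_W"] = (rng.standard_normal((f3, latent_dim)) * 0.01).astype(F32)
            for name in ("e_conv1", "e_conv2", "e_conv3"):
                P[name + "_b"] = np.zeros(P[name + "_W"].shape[2], dtype=F32)
            for name in ("e_fc1", "e_fc2", "e_fc3", "e_mu", "e_lv"):
                P[name + "_b"] = np.zeros(P[name + "_W"].shape[1], dtype=F32)

        P["d_fc1_W"] = he((d_in, f3), max(d_in, 1))
        P["d_fc2_W"] = he((f3, f2), f3)
        P["d_fc3_W"] = he((f2, f1), f2)
        P["d_proj_W"] = he((f1, Lc * c3), f1)
        P["d_conv1_W"] = he((self.k, c3, c2), self.k * c3)
        P["d_conv2_W"] = he((self.k, c2, c1), self.k * c2)
        P["d_conv3_W"] = he((self.k, c1, input_channels), self.k * c1)
        for name in ("d_fc1", "d_fc2", "d_fc3", "d_proj"):
            P[name + "_b"] = np.zeros(P[name + "_W"].shape[1], dtype=F32)
        for name in ("d_conv1", "d_conv2", "d_conv3"):
            P[name + "_b"] = np.zeros(P[name + "_W"].shape[2], dtype=F32)
        self.params = P

    # -- encoder ----------------------------------------------------------
    def encode_forward(self, x: Array, cache: bool = False):
        P = self.params
        caches = {}
        h = x
        for i in (1, 2, 3):
            h, caches[f"conv{i}"] = conv1d_forward(h, P[f"e_conv{i}_W"], P[f"e_conv{i}_b"])
            h, caches[f"pool{i}"] = maxpool_forward(h, self.p)
            h, caches[f"relu_c{i}"] = relu_forward(h)
        B = h.shape[0]
        caches["flat_shape"] = h.shape
        h = h.reshape(B, -1)
        for i in (1, 2, 3):
            h, caches[f"fc{i}"] = dense_forward(h, P[f"e_fc{i}_W"], P[f"e_fc{i}_b"])
            h, caches[f"relu_f{i}"] = relu_forward(h)
        mu, caches["mu"] = dense_forward(h, P["e_mu_W"], P["e_mu_b"])
        lv, caches["lv"] = dense_forward(h, P["e_lv_W"], P["e_lv_b"])
        lv = np.clip(lv, -10.0, 10.0)
        return (mu, lv, caches) if cache else (mu, lv)

    def encode_backward(self, dmu: Array, dlv: Array, caches, grads) -> None:
        P = self.params
        dh_mu, grads["e_mu_W"], grads["e_mu_b"] = dense_backward(dmu, caches["mu"], P["e_mu_W"])
        dh_lv, grads["e_lv_W"], grads["e_lv_b"] = dense_backward(dlv, caches["lv"], P["e_lv_W"])
        dh = dh_mu + dh_lv
        for i in (3, 2, 1):
            dh = relu_backward(dh, caches[f"relu_f{i}"])
            dh, grads[f"e_fc{i}_W"], grads[f"e_fc{i}_b"] = dense_backward(
                dh, caches[f"fc{i}"], P[f"e_fc{i}_W"]
            )
        dh = dh.reshape(caches["flat_shape"])
        for i in (3, 2, 1):
            dh = relu_backward(dh, caches[f"relu_c{i}"])
            dh = maxpool_backward(dh, caches[f"pool{i}"])
            dh, grads[f"e_conv{i}_W"], grads[f"e_conv{i}_b"] = conv1d_backward(
                dh, caches[f"conv{i}"]
            )

    # -- decoder ----------------------------------------------------------
    def decode_forward(self, z: Array, cache: bool = False):
        P = self.params
        caches = {}
        h = z
        for i in (1, 2, 3):
            h, caches[f"fc{i}"] = dense_forward(h, P[f"d_fc{i}_W"], P[f"d_fc{i}_b"])
            h, caches[f"relu_f{i}"] = relu_forward(h)
        h, caches["proj"] = dense_forward(h, P["d_proj_W"], P["d_proj_b"])
        h, caches["relu_p"] = relu_forward(h)
        B = h.shape[0]
        h = h.reshape(B, self.Lc, self.conv_channels[2])
        for i in (1, 2, 3):
            h, caches[f"up{i}"] = upsample_forward(h, self.p)
            h, caches[f"conv{i}"] = conv1d_forward(h, P[f"d_conv{i}_W"], P[f"d_conv{i}_b"])
            if i < 3:
                h, caches[f"relu_c{i}"] = relu_forward(h)
        caches["pre_crop_len"] = h.shape[1]
        h = h[:, : self.L, :]
        return (h, caches) if cache else h

    def decode_backward(self, dy: Array, caches, grads) -> Array:
        P = self.params
        pre = caches["pre_crop_len"]
        if pre > self.L:
            dy = np.pad(dy, ((0, 0), (0, pre - self.L), (0, 0)))
        dh = dy
        for i in (3, 2, 1):
            if i < 3:
                dh = relu_backward(dh, caches[f"relu_c{i}"])
            dh, grads[f"d_conv{i}_W"], grads[f"d_conv{i}_b"] = conv1d_backward(
                dh, caches[f"conv{i}"]
            )
            dh = upsample_backward(dh, caches[f"up{i}"])
        dh = dh.reshape(dh.shape[0], -1)
        dh = relu_backward(dh, caches["relu_p"])
        dh, grads["d_proj_W"], grads["d_proj_b"] = dense_backward(dh, caches["proj"], P["d_proj_W"])
        for i in (3, 2, 1):
            dh = relu_backward(dh, caches[f"relu_f{i}"])
            dh, grads[f"d_fc{i}_W"], grads[f"d_fc{i}_b"] = dense_backward(
                dh, caches[f"fc{i}"], P[f"d_fc{i}_W"]
            )
        return dh  # gradient w.r.t. decoder input z'


def vae_loss_and_grads(model: ConvVAE, x: Array, edfs: Array | None,
                       kl_weight: float, rng: np.random.Generator) -> Tuple[float, float, float, Dict[str, Array]]:
    """One minibatch forward/backward pass.

    Loss = mean squared reconstruction error (over batch, time, channels)
    + kl_weight * mean KL(posterior || N(0, I)); the KL applies only to
    the learned coordinates, never to injected features.
    """
    grads: Dict[str, Array] = {}
    B = x.shape[0]
    if model.latent_dim > 0:
        mu, lv, ec = model.encode_forward(x, cache=True)
        eps = rng.standard_normal(mu.shape).astype(F32)
        sigma = np.exp(0.5 * lv)
        z = mu + sigma * eps
        kl = float(0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0) / B)
    else:
        z = np.zeros((B, 0), dtype=F32)
        kl = 0.0
    zin = np.concatenate([z, edfs], axis=1) if model.n_injected else z
    xhat, dc = model.decode_forward(zin.astype(F32), cache=True)
    diff = xhat - x
    recon = float(np.mean(diff**2))
    dxhat = (2.0 / diff.size) * diff
    dzin = model.decode_backward(dxhat.astype(F32), dc, grads)
    if model.latent_dim > 0:
        dz = dzin[:, : model.latent_dim]
        dmu = dz + kl_weight * mu / B
        dlv = dz * eps * 0.5 * sigma + kl_weight * 0.5 * (np.exp(lv) - 1.0) / B
        model.encode_backward(dmu.astype(F32), dlv.astype(F32), ec, grads)
    return recon + kl_weight * kl, recon, kl, grads
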