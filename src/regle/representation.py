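"""Low-dimensional waveform encodings: conv-VAE, baselines, alignment.

The plain model encodes curves into ``latent_dim`` coordinates through a
convolutional variational autoencoder (posterior means are the GWAS
phenotypes).  The residual (feature-injected) variant concatenates five
z-scored expert features to the sampled latent before decoding, so the
coordinates capture only variation the features miss.  PCA and
single-knot cubic-spline embeddings serve as linear baselines, and
``align_latents`` matches latent spaces across training runs by a signed
permutation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA

from .nn import Adam, ConvVAE, F32, vae_loss_and_grads

__all__ = [
    "VAEConfig",
    "TrainedVAE",
    "LatentEncoding",
    "train_vae",
    "encode",
    "encode_table",
    "decode",
    "reconstruction_mse",
    "decoder_sweep",
    "align_latents",
    "PCABaseline",
    "pca_baseline",
    "spline_baseline",
]


@dataclass
class VAEConfig:
    """Architecture and training hyperparameters.

    The contract is the three-conv/three-dense mirror topology; the
    specific widths below are defaults and freely overridable.
    ``n_injected`` is 0 for the plain model and 5 for the residual one.
    """

    input_length: int = 1000
    input_channels: int = 2
    latent_dim: int = 5
    n_injected: int = 0
    conv_channels: Tuple[int, int, int] = (8, 16, 32)
    kernel_size: int = 5
    pool_size: int = 2
    fc_widths: Tuple[int, int, int] = (128, 64, 32)
    kl_weight: float = 1e-2
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.latent_dim < 0:
            raise ValueError("latent_dim must be nonnegative")
        if self.n_injected not in (0, 5):
            raise ValueError("n_injected must be 0 or 5")
        if self.latent_dim == 0 and self.n_injected == 0:
            raise ValueError("model needs latent or injected inputs")
        if len(self.conv_channels) != 3 or len(self.fc_widths) != 3:
            raise ValueError("three conv stages and three FC stages required")
        if min(self.kl_weight, self.learning_rate) <= 0:
            raise ValueError("kl_weight and learning_rate must be positive")
        if min(self.batch_size, self.epochs, self.input_length, self.input_channels) <= 0:
            raise ValueError("sizes must be positive")


@dataclass
class LatentEncoding:
    individual_id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("encoding coordinates must be finite")


@dataclass
class TrainedVAE:
    """A trained model with its config, training history and EDF scaler."""

    net: ConvVAE
    config: VAEConfig
    history: pd.DataFrame
    edf_mean: Optional[np.ndarray] = None
    edf_std: Optional[np.ndarray] = None

    def scale_edfs(self, edfs: np.ndarray) -> np.ndarray:
        if self.config.n_injected == 0:
            raise ValueError("model does not inject features")
        return ((np.asarray(edfs, dtype=float) - self.edf_mean) / self.edf_std).astype(F32)

    # -- persistence: json config + flat parameter arrays ----------------
    def save(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)
        arrays = dict(self.net.params)
        if self.edf_mean is not None:
            arrays["__edf_mean"] = self.edf_mean
            arrays["__edf_std"] = self.edf_std
        np.savez(os.path.join(directory, "params.npz"), **arrays)
        self.history.to_csv(os.path.join(directory, "history.csv"), index=False)

    @classmethod
    def load(cls, directory) -> "TrainedVAE":
        import os

        with open(os.path.join(directory, "config.json")) as fh:
            raw = json.load(fh)
        raw["conv_channels"] = tuple(raw["conv_channels"])
        raw["fc_widths"] = tuple(raw["fc_widths"])
        config = VAEConfig(**raw)
        net = _build_net(config)
        data = np.load(os.path.join(directory, "params.npz"))
        edf_mean = edf_std = None
        for key in data.files:
            if key == "__edf_mean":
                edf_mean = data[key]
            elif key == "__edf_std":
                edf_std = data[key]
            else:
                net.params[key] = data[key]
        history = pd.read_csv(os.path.join(directory, "history.csv"))
        return cls(net=net, config=config, history=history,
                   edf_mean=edf_mean, edf_std=edf_std)


def _build_net(config: VAEConfig) -> ConvVAE:
    return ConvVAE(
        input_length=config.input_length,
        input_channels=config.input_channels,
        latent_dim=config.latent_dim,
        n_injected=config.n_injected,
        conv_channels=config.conv_channels,
        kernel_size=config.kernel_size,
        pool_size=config.pool_size,
        fc_widths=config.fc_widths,
        seed=config.seed,
    )


def _as_batch(curves: np.ndarray, config: VAEConfig) -> np.ndarray:
    """Accept (n, L) single-channel or (n, L, C) arrays."""
    x = np.asarray(curves, dtype=F32)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.shape[1] != config.input_length or x.shape[2] != config.input_channels:
        raise ValueError(
            f"curves shaped {x.shape[1:]} but config expects "
            f"({config.input_length}, {config.input_channels})"
        )
    return x


def train_vae(
    curves: np.ndarray,
    edfs: Optional[np.ndarray] = None,
    config: VAEConfig = VAEConfig(),
    validation: Optional[Tuple[np.ndarray, Optional[np.ndarray]]] = None,
) -> TrainedVAE:
    """Fit the model by Adam on MSE + kl_weight * KL for ``config.epochs``.

    ``edfs`` (n x 5) must be supplied iff ``config.n_injected == 5``;
    they are z-scored with training-set statistics before concatenation
    to the sampled latent.  No early stopping; validation loss, when a
    validation split is given, is recorded per epoch for hyperparameter
    choice only.  Deterministic given ``config.seed``.
    """
    config.validate()
    x = _as_batch(curves, config)
    n = x.shape[0]
    edf_mean = edf_std = None
    e = None
    if config.n_injected:
        if edfs is None:
            raise ValueError("config injects features but none were supplied")
        edfs = np.asarray(edfs, dtype=float)
        if edfs.shape != (n, config.n_injected):
            raise ValueError("edfs must be (n_curves, n_injected)")
        edf_mean = edfs.mean(axis=0)
        edf_std = edfs.std(axis=0)
        edf_std[edf_std == 0] = 1.0
        e = ((edfs - edf_mean) / edf_std).astype(F32)
    elif edfs is not None:
        raise ValueError("edfs supplied but config.n_injected == 0")

    net = _build_net(config)
    # start the decoder output at the per-channel data mean: removes the
    # DC component of the loss before the first step
    net.params["d_conv3_b"][:] = x.mean(axis=(0, 1))
    opt = Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    model = TrainedVAE(net=net, config=config, history=pd.DataFrame(),
                       edf_mean=edf_mean, edf_std=edf_std)
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        tot = rec = kl = 0.0
        nb = 0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb = x[sel]
            eb = e[sel] if e is not None else None
            loss, r, k, grads = vae_loss_and_grads(net, xb, eb, config.kl_weight, rng)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {nb}: "
                    f"recon={r}, kl={k}; lower the learning rate"
                )
            opt.step(net.params, grads)
            tot += loss
            rec += r
            kl += k
            nb += 1
        row = {
            "epoch": epoch,
            "train_loss": tot / nb,
            "train_recon": rec / nb,
            "train_kl": kl / nb,
        }
        if validation is not None:
            vx, ve = validation
            row["val_recon"] = float(np.mean(reconstruction_mse(model, vx, ve)["per_curve"]))
        rows.append(row)
    model.history = pd.DataFrame(rows)
    return model


def encode(model: TrainedVAE, curves: np.ndarray) -> np.ndarray:
    """Posterior-mean coordinates (deterministic; no sampling)."""
    if model.config.latent_dim == 0:
        raise ValueError("decoder-only model has no encoder")
    x = _as_batch(curves, model.config)
    out = []
    for start in range(0, x.shape[0], 1024):
        mu, _ = model.net.encode_forward(x[start : start + 1024])
        out.append(mu)
    return np.concatenate(out, axis=0).astype(float)


def encode_table(model: TrainedVAE, curves: np.ndarray, ids: Sequence[str]) -> pd.DataFrame:
    coords = encode(model, curves)
    cols = [f"coord_{k + 1}" for k in range(coords.shape[1])]
    return pd.DataFrame(coords, index=list(ids), columns=cols)


def decode(model: TrainedVAE, coords: np.ndarray,
           edfs: Optional[np.ndarray] = None) -> np.ndarray:
    """Curves decoded from latent coordinates (+ raw-scale EDFs if injected)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] != model.config.latent_dim:
        raise ValueError("coords width must equal latent_dim")
    if model.config.n_injected:
        if edfs is None:
            raise ValueError("residual model requires the injected features")
        e = model.scale_edfs(np.atleast_2d(edfs))
        if e.shape[0] == 1 and coords.shape[0] > 1:
            e = np.repeat(e, coords.shape[0], axis=0)
        zin = np.concatenate([coords, e], axis=1)
    else:
        if edfs is not None:
            raise ValueError("plain model takes no injected features")
        zin = coords
    out = model.net.decode_forward(zin.astype(F32))
    return out.astype(float)


def reconstruction_mse(model, curves: np.ndarray,
                       edfs: Optional[np.ndarray] = None) -> Dict[str, np.ndarray]:
    """Per-curve mean squared error across time points (and channels).

    ``model`` may be a TrainedVAE (encode -> decode, injecting features
    when configured) or any object with ``transform``/``inverse_transform``
    (the PCA baseline).
    """
    if isinstance(model, TrainedVAE):
        x = _as_batch(curves, model.config)
        if model.config.latent_dim > 0:
            coords = encode(model, curves)
        else:
            coords = np.zeros((x.shape[0], 0))
        xhat = decode(model, coords, edfs if model.config.n_injected else None)
    else:
        x = np.asarray(curves, dtype=float)
        if x.ndim == 2:
            x = x[:, :, None]
        flat = x.reshape(x.shape[0], -1)
        xhat = model.inverse_transform(model.transform(flat)).reshape(x.shape)
    if x.shape[0] == 0:
        raise ValueError("empty dataset")
    per_curve = np.mean((np.asarray(xhat, dtype=float) - x) ** 2, axis=(1, 2))
    return {"per_curve": per_curve, "mean": float(per_curve.mean())}


def decoder_sweep(model: TrainedVAE, edfs: np.ndarray, coord_index: int,
                  values: Sequence[float]) -> np.ndarray:
    """Decode curves varying one coordinate, all others fixed at zero.

    Requires the residual (feature-injecting) model; ``edfs`` is one raw
    feature vector held fixed across the sweep.
    """
    if model.config.n_injected == 0:
        raise ValueError("decoder_sweep requires the residual model")
    d = model.config.latent_dim
    if not (0 <= coord_index < d):
        raise ValueError("coord_index out of range")
    coords = np.zeros((len(values), d))
    coords[:, coord_index] = np.asarray(values, dtype=float)
    return decode(model, coords, np.atleast_2d(edfs))


def align_latents(A: pd.DataFrame, B: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match B's coordinates to A's by a signed permutation.

    Returns (permutation, signs, matched |r|): coordinate k of A pairs
    with coordinate ``permutation[k]`` of B with sign ``signs[k]``, chosen
    to maximize the total |Pearson r| by linear assignment on the
    absolute correlation matrix.
    """
    shared = A.index.intersection(B.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared individuals")
    a = A.loc[shared].to_numpy(dtype=float)
    b = B.loc[shared].to_numpy(dtype=float)
    d = a.shape[1]
    if b.shape[1] != d:
        raise ValueError("latent dimensions differ")
    r = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            r[i, j] = np.corrcoef(a[:, i], b[:, j])[0, 1]
    row, col = linear_sum_assignment(-np.abs(r))
    perm = np.empty(d, dtype=int)
    perm[row] = col
    signs = np.sign(r[row, col]).astype(int)
    signs[signs == 0] = 1
    matched = np.abs(r[np.arange(d), perm])
    return perm, signs, matched


class PCABaseline:
    """Top-k PCA of flattened (possibly multi-channel) curves."""

    def __init__(self, k: int):
        if k <= 0:
            raise ValueError("k must be positive")
        self.k = k
        self._pca = PCA(n_components=k, svd_solver="full")
        self._shape: Optional[Tuple[int, ...]] = None

    def fit(self, curves: np.ndarray) -> "PCABaseline":
        x = np.asarray(curves, dtype=float)
        if x.ndim == 2:
            x = x[:, :, None]
        self._shape = x.shape[1:]
        self._pca.fit(x.reshape(x.shape[0], -1))
        return self

    def transform(self, flat: np.ndarray) -> np.ndarray:
        return self._pca.transform(np.asarray(flat, dtype=float))

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return self._pca.inverse_transform(scores)

    @property
    def components_(self) -> np.ndarray:
        return self._pca.components_


def pca_baseline(train_curves: np.ndarray, k: int) -> PCABaseline:
    """Fit the linear embedding baseline on concatenated channels."""
    return PCABaseline(k).fit(train_curves)


def spline_baseline(volume_values: np.ndarray) -> np.ndarray:
    """Five least-squares coefficients of a one-knot cubic spline.

    Basis: {1, t, t^2, t^3, (t - 0.2)^3_+} on t in [0, 1], the knot at
    the 20% position of the time axis; exactly five free coefficients.
    """
    v = np.asarray(volume_values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expects a single volume trace")
    t = np.linspace(0.0, 1.0, len(v))
    basis = np.column_stack(
        [np.ones_like(t), t, t**2, t**3, np.clip(t - 0.2, 0.0, None) ** 3]
    )
    coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
    return coef
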