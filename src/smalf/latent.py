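"""Stacked autoencoder for latent features of miRNAs and diseases.

Each row of the association matrix is a miRNA's original feature vector and
each column (transposed) a disease's. A stacked autoencoder compresses these
sparse binary vectors into dense low-dimensional codes: the encoder applies
``h^(l) = f_e(W^l h^(l-1) + b^l)`` for the hidden layers and a *linear* code
layer ``z = W^L h^(L-1) + b^L``; the decoder mirrors the stack with
activation ``f_d`` and a hyperbolic-tangent output layer. Training is greedy
layerwise pretraining of each sub-autoencoder followed by end-to-end
fine-tuning of the loss

    sum_i ||x_i - xhat_i||^2 + lambda * ||J_h(x_i)||^2

where ``J_h`` is the Jacobian of the first hidden layer's activations with
respect to the input (a contractive penalty). Everything runs in numpy with
hand-written backpropagation and an Adam optimizer, fully deterministic for
a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_data import AssociationDataset

__all__ = [
    "AutoencoderConfig",
    "EncoderModel",
    "LatentFeatures",
    "split_original_features",
    "train_stacked_autoencoder",
    "encode",
    "reconstruction_loss",
]

# ---------------------------------------------------------------------------
# activations


def _act(name: str, a: np.ndarray) -> np.ndarray:
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-a))
    if name == "tanh":
        return np.tanh(a)
    if name == "linear":
        return a
    raise ValueError(f"unknown activation {name!r}")


def _act_deriv(name: str, h: np.ndarray) -> np.ndarray:
    """Derivative of the activation expressed through its output ``h``."""
    if name == "sigmoid":
        return h * (1.0 - h)
    if name == "tanh":
        return 1.0 - h**2
    if name == "linear":
        return np.ones_like(h)
    raise ValueError(f"unknown activation {name!r}")


def _act_second_deriv(name: str, h: np.ndarray) -> np.ndarray:
    """Second derivative through the output (for the contractive penalty)."""
    if name == "sigmoid":
        return h * (1.0 - h) * (1.0 - 2.0 * h)
    if name == "tanh":
        return -2.0 * h * (1.0 - h**2)
    if name == "linear":
        return np.zeros_like(h)
    raise ValueError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# configuration and containers


@dataclasses.dataclass(frozen=True)
class AutoencoderConfig:
    """Hyperparameters of the two-hidden-layer stacked autoencoder.

    ``hidden_dims`` lists the encoder layer widths and must end in
    ``latent_dim``; the decoder mirrors it. ``jacobian_weight`` is the
    contractive-penalty coefficient lambda.
    """

    latent_dim: int = 64
    hidden_dims: tuple[int, ...] = (256, 64)
    jacobian_weight: float = 1e-4
    encoder_activation: str = "sigmoid"
    decoder_activation: str = "sigmoid"
    epochs_pretrain: int = 200
    epochs_finetune: int = 800
    learning_rate: float = 3e-3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_dims", tuple(self.hidden_dims))
        if not self.hidden_dims or self.hidden_dims[-1] != self.latent_dim:
            raise ValueError(
                f"hidden_dims {self.hidden_dims} must end in latent_dim {self.latent_dim}"
            )
        if self.jacobian_weight < 0:
            raise ValueError("jacobian_weight must be non-negative")

    @classmethod
    def scaled(cls, input_dim: int, seed: int = 0, **overrides) -> "AutoencoderConfig":
        """Scale the default [256, 64] architecture to a smaller input width.

        Widths follow the same proportions as the defaults on a 383-wide
        input, rounded down to powers of two (minimum 4).
        """
        def pow2(x: float) -> int:
            return max(4, 2 ** int(math.floor(math.log2(max(x, 4.0)))))

        hidden = pow2(input_dim * 256.0 / 383.0)
        latent = pow2(input_dim * 64.0 / 383.0)
        latent = min(latent, hidden)
        defaults = dict(latent_dim=latent, hidden_dims=(hidden, latent), seed=seed)
        defaults.update(overrides)
        return cls(**defaults)


@dataclasses.dataclass(frozen=True)
class LatentFeatures:
    """Entity -> dense latent vector table, rows aligned with ``ids``."""

    ids: tuple[str, ...]
    Z: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        Z = np.asarray(self.Z, dtype=float)
        if Z.ndim != 2 or Z.shape[0] != len(self.ids):
            raise ValueError(f"Z shape {Z.shape} does not match {len(self.ids)} ids")
        if not np.isfinite(Z).all():
            raise ValueError("latent features contain non-finite values")
        object.__setattr__(self, "Z", Z)

    @property
    def latent_dim(self) -> int:
        return self.Z.shape[1]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.Z, index=list(self.ids)).to_csv(path)


class EncoderModel:
    """Trained stacked autoencoder: encoder + decoder layer stacks.

    Layers are ``(W, b, activation)`` triples; ``W`` has shape
    ``(fan_out, fan_in)`` and layers apply ``act(W @ x + b)`` row-wise.
    """

    def __init__(
        self,
        encoder: list[tuple[np.ndarray, np.ndarray, str]],
        decoder: list[tuple[np.ndarray, np.ndarray, str]],
        config: AutoencoderConfig,
    ) -> None:
        self.encoder = encoder
        self.decoder = decoder
        self.config = config
        self.pretrain_losses: list[list[float]] = []
        self.finetune_losses: list[float] = []

    @property
    def input_dim(self) -> int:
        return self.encoder[0][0].shape[1]

    @property
    def latent_dim(self) -> int:
        return self.encoder[-1][0].shape[0]

    def _forward(self, X: np.ndarray, layers) -> list[np.ndarray]:
        acts = [X]
        for W, b, act in layers:
            acts.append(_act(act, acts[-1] @ W.T + b))
        return acts

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"input width {X.shape[1]} does not match encoder width {self.input_dim}"
            )
        return self._forward(X, self.encoder)[-1]

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._forward(self.encode(X), self.decoder)[-1]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for tag, layers in (("enc", self.encoder), ("dec", self.decoder)):
            for i, (W, b, _) in enumerate(layers):
                arrays[f"{tag}{i}_W"] = W
                arrays[f"{tag}{i}_b"] = b
        meta = {
            "config": dataclasses.asdict(self.config),
            "enc_acts": [a for _, _, a in self.encoder],
            "dec_acts": [a for _, _, a in self.decoder],
        }
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            enc = [
                (data[f"enc{i}_W"], data[f"enc{i}_b"], a)
                for i, a in enumerate(meta["enc_acts"])
            ]
            dec = [
                (data[f"dec{i}_W"], data[f"dec{i}_b"], a)
                for i, a in enumerate(meta["dec_acts"])
            ]
        return cls(enc, dec, AutoencoderConfig(**meta["config"]))


# ---------------------------------------------------------------------------
# operations


def split_original_features(dataset: AssociationDataset) -> tuple[np.ndarray, np.ndarray]:
    """Decompose Y into original feature matrices M (rows) and D (columns).

    ``M[i]`` is miRNA i's length-``n_disease`` profile (row i of Y);
    ``D[j]`` is disease j's length-``n_mirna`` profile (column j of Y).
    """
    Y = dataset.Y.astype(float)
    return Y.copy(), Y.T.copy()


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _penalty_value(X: np.ndarray, h1: np.ndarray, W1: np.ndarray, act: str) -> float:
    """sum_i ||J_h(x_i)||_F^2 for the first layer h = act(W1 x + b1)."""
    phi1 = _act_deriv(act, h1)  # (n, hidden)
    wnorm = (W1**2).sum(axis=1)  # (hidden,)
    return float((phi1**2 @ wnorm).sum())


def _penalty_grads(
    X: np.ndarray, h1: np.ndarray, W1: np.ndarray, act: str
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the summed Jacobian penalty w.r.t. (W1, b1)."""
    phi1 = _act_deriv(act, h1)
    phi2 = _act_second_deriv(act, h1)
    wnorm = (W1**2).sum(axis=1)
    # d/dW direct term: 2 * sum_i phi1_ij^2 * W_jk
    gW = 2.0 * (phi1**2).sum(axis=0)[:, None] * W1
    # pre-activation route: dP/da_ij = 2 phi1 phi2 * ||W_j||^2
    delta = 2.0 * phi1 * phi2 * wnorm[None, :]
    gW += delta.T @ X
    gb = delta.sum(axis=0)
    return gW, gb


def _ae_loss_and_grads(
    X: np.ndarray,
    layers: list[tuple[np.ndarray, np.ndarray, str]],
    lam: float,
) -> tuple[float, list[np.ndarray]]:
    """Squared-error reconstruction loss + contractive penalty and its gradients.

    ``layers`` is the full encode+decode stack applied to ``X``; the penalty
    attaches to the first layer.
    """
    acts = [X]
    for W, b, act in layers:
        acts.append(_act(act, acts[-1] @ W.T + b))
    xhat = acts[-1]
    resid = xhat - X
    loss = float((resid**2).sum())

    grads: list[np.ndarray] = [np.zeros(0)] * (2 * len(layers))
    delta = 2.0 * resid  # dL/d(output)
    for li in range(len(layers) - 1, -1, -1):
        W, b, act = layers[li]
        delta = delta * _act_deriv(act, acts[li + 1])  # dL/d(pre-activation)
        grads[2 * li] = delta.T @ acts[li]
        grads[2 * li + 1] = delta.sum(axis=0)
        delta = delta @ W

    if lam > 0:
        W1, b1, act1 = layers[0]
        h1 = acts[1]
        loss += lam * _penalty_value(X, h1, W1, act1)
        gW, gb = _penalty_grads(X, h1, W1, act1)
        grads[0] = grads[0] + lam * gW
        grads[1] = grads[1] + lam * gb
    return loss, grads


def _init_layer(rng: np.random.Generator, fan_out: int, fan_in: int):
    scale = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
    W = rng.uniform(-scale, scale, size=(fan_out, fan_in))
    b = np.zeros(fan_out)
    return W, b


def _train_layers(
    X: np.ndarray,
    layers: list[tuple[np.ndarray, np.ndarray, str]],
    lam: float,
    epochs: int,
    lr: float,
    phase: str,
) -> list[float]:
    params: list[np.ndarray] = []
    for W, b, _ in layers:
        params.extend([W, b])
    opt = _Adam(params, lr)
    history = []
    for epoch in range(epochs):
        loss, grads = _ae_loss_and_grads(X, layers, lam)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at {phase} epoch {epoch}")
        opt.step(grads)
        history.append(loss)
    return history


def train_stacked_autoencoder(
    X: np.ndarray, config: AutoencoderConfig
) -> EncoderModel:
    """Greedy layerwise pretraining then end-to-end fine-tuning.

    Each sub-autoencoder is pretrained on the previous layer's codes; the
    assembled stack is then fine-tuned jointly. Loss trajectories are stored
    on the returned model (``pretrain_losses`` per layer, ``finetune_losses``).
    Full-batch training; reproducible for a fixed ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("input matrix is empty")
    input_dim = X.shape[1]
    if config.latent_dim >= input_dim:
        warnings.warn(
            f"latent_dim {config.latent_dim} >= input width {input_dim}: no compression",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    widths = [input_dim, *config.hidden_dims]

    encoder: list[tuple[np.ndarray, np.ndarray, str]] = []
    decoder_rev: list[tuple[np.ndarray, np.ndarray, str]] = []
    pretrain_losses: list[list[float]] = []
    H = X
    n_layers = len(config.hidden_dims)
    for l in range(n_layers):
        fan_in, fan_out = widths[l], widths[l + 1]
        is_code = l == n_layers - 1
        enc_act = "linear" if is_code else config.encoder_activation
        # the outermost decoder layer reconstructs the raw input through tanh
        dec_act = "tanh" if l == 0 else config.decoder_activation
        We, be = _init_layer(rng, fan_out, fan_in)
        Wd, bd = _init_layer(rng, fan_in, fan_out)
        sub = [(We, be, enc_act), (Wd, bd, dec_act)]
        history = _train_layers(
            H, sub, config.jacobian_weight, config.epochs_pretrain,
            config.learning_rate, phase=f"pretrain layer {l + 1}",
        )
        pretrain_losses.append(history)
        encoder.append((We, be, enc_act))
        decoder_rev.append((Wd, bd, dec_act))
        H = _act(enc_act, H @ We.T + be)

    layers = encoder + decoder_rev[::-1]
    finetune_losses = _train_layers(
        X, layers, config.jacobian_weight, config.epochs_finetune,
        config.learning_rate, phase="fine-tune",
    )

    model = EncoderModel(encoder, decoder_rev[::-1], config)
    model.pretrain_losses = pretrain_losses
    model.finetune_losses = finetune_losses
    return model


def encode(
    model: EncoderModel, X: np.ndarray, ids: Sequence[str] | None = None
) -> LatentFeatures:
    """Apply the trained encoder; rows of the result align with rows of X."""
    Z = model.encode(np.asarray(X, dtype=float))
    if ids is None:
        ids = tuple(str(i) for i in range(Z.shape[0]))
    return LatentFeatures(tuple(ids), Z)


def reconstruction_loss(model: EncoderModel, X: np.ndarray, lam: float | None = None) -> float:
    """Summed squared reconstruction error plus the Jacobian penalty."""
    X = np.asarray(X, dtype=float)
    if lam is None:
        lam = model.config.jacobian_weight
    layers = model.encoder + model.decoder
    loss, _ = _ae_loss_and_grads(X, layers, lam)
    return loss
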