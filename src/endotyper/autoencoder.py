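"""Two-dimensional autoencoder embedding of the normalized clustering variables.

A symmetric multilayer perceptron (default 4→64→32→16→2 encoder, mirrored
decoder; tanh hidden layers, linear bottleneck and output) trained to
minimize mean squared reconstruction error with mini-batch Adam.  The two
bottleneck activations are the latent representation in which endotypes
are clustered.  By default the latent is anchored to the data's top-2
principal-component chart throughout training (see
:class:`AutoencoderConfig`), which makes the embedding — and everything
clustered on it — reproducible across initializations.  Training is
label-free and fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, TrainingError

LATENT_DIM = 2


@dataclass(frozen=True)
class AutoencoderConfig:
    """Training settings.

    The default encoder (4→64→32→16→2, mirrored decoder) is deliberately
    over-parameterized for a 4-variable input: folding a full-rank
    4-dimensional mixture through a 2-D bottleneck needs a flexible
    nonlinear surface, and narrow encoders lose cluster structure.
    ``n_restarts`` independent trainings are run and the one with the best
    monitored (validation) reconstruction loss is kept — reconstruction
    quality is label-free, so this is ordinary unsupervised model selection.

    An unconstrained 2-D bottleneck is identifiable only up to an arbitrary
    diffeomorphism of the latent plane, so different initializations land in
    reconstruction-equivalent but geometrically very different embeddings —
    and the downstream clustering inherits that irreproducibility.  The
    latent is therefore penalized toward the data's top-2 principal-
    component scores (a canonical, variance-ordered chart) with weight
    ``pca_anchor_weight`` for the first ``pca_anchor_epochs`` epochs; the
    default keeps a strong anchor on for the whole run, so the encoder
    stays close to the principal chart while the decoder learns a free
    nonlinear reconstruction from it.  The anchor is computed from the
    training data alone (no labels); weight 0 recovers the unconstrained
    autoencoder.
    """

    hidden: tuple[int, ...] = (64, 32, 16)
    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    patience: int = 10
    n_restarts: int = 2
    pca_anchor_epochs: int = 200
    pca_anchor_weight: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden):
            raise ConfigError("all hidden sizes must be >= 1")
        if not (0 <= self.val_fraction < 1):
            raise ConfigError("val_fraction must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigError("epochs, batch_size >= 1 and learning_rate > 0 required")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")
        if self.pca_anchor_epochs < 0 or self.pca_anchor_weight < 0:
            raise ConfigError("pca_anchor_epochs and pca_anchor_weight must be >= 0")

    def to_dict(self) -> dict:
        return {
            "hidden": list(self.hidden),
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "val_fraction": self.val_fraction,
            "patience": self.patience,
            "n_restarts": self.n_restarts,
            "pca_anchor_epochs": self.pca_anchor_epochs,
            "pca_anchor_weight": self.pca_anchor_weight,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AutoencoderConfig":
        d = dict(d)
        if "hidden" in d:
            d["hidden"] = tuple(d["hidden"])
        return cls(**d)


@dataclass
class EncoderModel:
    """Fitted autoencoder: layer weights plus the training history.

    ``weights``/``biases`` hold all layers encoder-first; the first
    ``n_encoder_layers`` map input → latent.  Hidden layers use tanh, the
    bottleneck and the reconstruction output are linear.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    n_encoder_layers: int
    history: pd.DataFrame = field(repr=False)
    config: AutoencoderConfig = field(default_factory=AutoencoderConfig)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    @property
    def latent_dim(self) -> int:
        return self.weights[self.n_encoder_layers - 1].shape[1]

    def to_dict(self) -> dict:
        return {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "n_encoder_layers": self.n_encoder_layers,
            "config": self.config.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderModel":
        return cls(
            weights=[np.array(w, dtype=float) for w in d["weights"]],
            biases=[np.array(b, dtype=float) for b in d["biases"]],
            n_encoder_layers=int(d["n_encoder_layers"]),
            history=pd.DataFrame(columns=["epoch", "train_loss", "val_loss"]),
            config=AutoencoderConfig.from_dict(d["config"]) if "config" in d else AutoencoderConfig(),
        )


def _forward(weights, biases, X, n_layers_total, up_to=None):
    """Forward pass returning pre- and post-activation values per layer."""
    acts = [X]
    stop = n_layers_total if up_to is None else up_to
    h = X
    for li in range(stop):
        z = h @ weights[li] + biases[li]
        # linear on the bottleneck and the final output, tanh elsewhere
        last_of_half = li == len(weights) // 2 - 1 or li == len(weights) - 1
        h = z if last_of_half else np.tanh(z)
        acts.append(h)
    return acts


def encode(model: EncoderModel, points) -> np.ndarray:
    """Map normalized 4-vectors to the 2-D latent space (encoder layers only)."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.input_dim:
        raise DataError(f"expected {model.input_dim}-dim input, got {X.shape[1]}")
    return _forward(model.weights, model.biases, X, len(model.weights), up_to=model.n_encoder_layers)[-1]


def decode(model: EncoderModel, latent) -> np.ndarray:
    """Map latent 2-vectors back to the normalized variable space."""
    Z = np.asarray(latent, dtype=float)
    if Z.ndim == 1:
        Z = Z[None, :]
    h = Z
    nw = len(model.weights)
    for li in range(model.n_encoder_layers, nw):
        z = h @ model.weights[li] + model.biases[li]
        h = z if li == nw - 1 else np.tanh(z)
    return h


def reconstruct(model: EncoderModel, points) -> np.ndarray:
    return decode(model, encode(model, points))


def reconstruction_mse(model: EncoderModel, points) -> float:
    X = np.asarray(points, dtype=float)
    R = reconstruct(model, X)
    return float(np.mean((R - X) ** 2))


def train_autoencoder(points, cfg: AutoencoderConfig = AutoencoderConfig()) -> EncoderModel:
    """Train the autoencoder on normalized points by mini-batch Adam.

    Runs ``cfg.n_restarts`` independent trainings (different weight
    initializations and batch orders, same train/validation split) and
    returns the one with the lowest monitored reconstruction loss.  Early
    stopping monitors validation loss with the configured patience and
    restores the best weights; with ``val_fraction=0`` training runs the
    full epoch budget.  Deterministic under a fixed seed.  Raises
    :class:`DataError` on non-finite input and :class:`TrainingError` if
    the loss diverges.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise DataError("points must be a 2-D array")
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite values in training data")
    n, d = X.shape
    if n < 100:
        raise DataError(f"need >= 100 points to train, got {n}")

    base_rng = np.random.default_rng(cfg.seed)
    perm = base_rng.permutation(n)
    n_val = int(round(n * cfg.val_fraction))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, Xval = X[train_idx], X[val_idx]

    # top-2 principal-component scores of the training split: the latent
    # anchor target during the warm-up phase (label-free, variance-ordered)
    anchor = None
    if cfg.pca_anchor_epochs > 0 and cfg.pca_anchor_weight > 0:
        center = Xtr.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xtr - center, full_matrices=False)
        anchor = (Xtr - center) @ Vt[:LATENT_DIM].T

    best_model = None
    best_monitor = np.inf
    for _ in range(cfg.n_restarts):
        rng = np.random.default_rng(int(base_rng.integers(2**31)))
        model, monitor = _train_once(Xtr, Xval, d, cfg, rng, anchor)
        if monitor < best_monitor:
            best_monitor = monitor
            best_model = model
    return best_model


def _train_once(Xtr, Xval, d, cfg: AutoencoderConfig, rng, anchor=None) -> tuple[EncoderModel, float]:
    n_val = len(Xval)
    sizes = [d, *cfg.hidden, LATENT_DIM, *reversed(cfg.hidden), d]
    n_layers = len(sizes) - 1
    n_enc = len(cfg.hidden) + 1
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))

    # Adam state
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    hist = {"epoch": [], "train_loss": [], "val_loss": []}
    best_val = np.inf
    best = None
    wait = 0
    ntr = len(Xtr)

    for epoch in range(cfg.epochs):
        anchored = anchor is not None and epoch < cfg.pca_anchor_epochs
        order = rng.permutation(ntr)
        for s in range(0, ntr, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            batch = Xtr[idx]
            acts = _forward(weights, biases, batch, n_layers)
            out = acts[-1]
            m = batch.shape[0]
            delta = 2.0 * (out - batch) / (m * d)  # dMSE/dout
            grads_w = [None] * n_layers
            grads_b = [None] * n_layers
            for li in range(n_layers - 1, -1, -1):
                linear = li == n_layers // 2 - 1 or li == n_layers - 1
                if not linear:
                    delta = delta * (1.0 - acts[li + 1] ** 2)  # tanh'
                if anchored and li == n_enc - 1:
                    # pull the (linear) bottleneck toward the PCA scores
                    delta = delta + cfg.pca_anchor_weight * 2.0 * (
                        acts[n_enc] - anchor[idx]
                    ) / (m * LATENT_DIM)
                grads_w[li] = acts[li].T @ delta
                grads_b[li] = delta.sum(axis=0)
                if li:
                    delta = delta @ weights[li].T
            t += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for li in range(n_layers):
                mw[li] = beta1 * mw[li] + (1 - beta1) * grads_w[li]
                vw[li] = beta2 * vw[li] + (1 - beta2) * grads_w[li] ** 2
                weights[li] -= lr_t * mw[li] / (np.sqrt(vw[li]) + eps)
                mb[li] = beta1 * mb[li] + (1 - beta1) * grads_b[li]
                vb[li] = beta2 * vb[li] + (1 - beta2) * grads_b[li] ** 2
                biases[li] -= lr_t * mb[li] / (np.sqrt(vb[li]) + eps)

        train_loss = float(np.mean((_forward(weights, biases, Xtr, n_layers)[-1] - Xtr) ** 2))
        val_loss = (
            float(np.mean((_forward(weights, biases, Xval, n_layers)[-1] - Xval) ** 2))
            if n_val
            else np.nan
        )
        if not np.isfinite(train_loss):
            raise TrainingError(f"training loss diverged at epoch {epoch}")
        hist["epoch"].append(epoch)
        hist["train_loss"].append(train_loss)
        hist["val_loss"].append(val_loss)

        if anchored:
            continue  # best-weights tracking and patience start after the warm-up
        monitor = val_loss if n_val else train_loss
        if monitor < best_val - 1e-12:
            best_val = monitor
            best = ([w.copy() for w in weights], [b.copy() for b in biases])
            wait = 0
        else:
            wait += 1
            if n_val and cfg.patience and wait >= cfg.patience:
                break

    if best is not None:
        weights, biases = best
    elif hist["train_loss"]:
        # run ended inside the anchored warm-up: keep the final weights
        best_val = hist["val_loss"][-1] if n_val else hist["train_loss"][-1]
    model = EncoderModel(
        weights=weights,
        biases=biases,
        n_encoder_layers=n_enc,
        history=pd.DataFrame(hist),
        config=cfg,
    )
    return model, float(best_val)
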