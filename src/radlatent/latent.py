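"""Per-mask autoencoder compression of radiomic feature blocks.

Each ROI mask's standardized feature block (width ``D``) is compressed by a
shallow dense autoencoder: the encoder halves the width and then squeezes
to the bottleneck ``d`` (widths ``[D, floor(D/2), d]``), the decoder
mirrors it back.  Hidden (halving) layers use a rectifier; the bottleneck
and reconstruction outputs are linear, appropriate for mean-squared
reconstruction of z-scored real values.  Training minimizes per-cell MSE
with Adam, mini-batches, and early stopping on the training loss; a grid
search over bottleneck sizes picks the smallest latent dimension whose
final reconstruction error falls below a threshold (0.2 of standardized
variance by default).

The network is implemented directly in numpy: the model is tiny (two dense
layers each way), and an explicit implementation keeps initialisation,
shuffling and the epoch loss history bit-reproducible from a single seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from ._seeds import derive_seed


@dataclass(frozen=True)
class EncoderSpec:
    """Layer widths of the encoder; the decoder mirrors them exactly."""

    layer_widths: tuple[int, int, int]  # (D, floor(D/2), d)

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.layer_widths):
            raise ValueError(f"layer widths must be >= 1, got {self.layer_widths}")

    @property
    def input_dim(self) -> int:
        return self.layer_widths[0]

    @property
    def hidden_dim(self) -> int:
        return self.layer_widths[1]

    @property
    def latent_dim(self) -> int:
        return self.layer_widths[2]

    @property
    def decoder_widths(self) -> tuple[int, int, int]:
        return tuple(reversed(self.layer_widths))


def build_autoencoder(input_dim: int, latent_dim: int) -> EncoderSpec:
    """Widths ``[D, floor(D/2), d]`` with a mirrored decoder.

    For the study's per-mask width 535 this gives the halving layer width
    267.
    """
    if latent_dim < 1 or latent_dim > input_dim:
        raise ValueError(
            f"latent_dim must be in [1, input_dim]; got latent_dim="
            f"{latent_dim}, input_dim={input_dim}")
    return EncoderSpec((int(input_dim), int(input_dim) // 2 or 1,
                        int(latent_dim)))


@dataclass(frozen=True)
class TrainConfig:
    """Autoencoder training hyperparameters.

    Defaults: 250 max epochs, Adam at 1e-3, batch 32, early stopping with
    patience 10 epochs and min-delta 1e-4 on the training loss.
    """

    max_epochs: int = 250
    learning_rate: float = 1e-3
    batch_size: int = 32
    patience: int = 10
    min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if not self.patience < self.max_epochs:
            raise ValueError(
                f"patience ({self.patience}) must be < max_epochs "
                f"({self.max_epochs})")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_weights(spec: EncoderSpec, rng: np.random.Generator) -> dict:
    D, h, d = spec.layer_widths
    return {
        "W1": _glorot(rng, D, h), "b1": np.zeros(h),
        "W2": _glorot(rng, h, d), "b2": np.zeros(d),
        "W3": _glorot(rng, d, h), "b3": np.zeros(h),
        "W4": _glorot(rng, h, D), "b4": np.zeros(D),
    }


def _forward(w: dict, X: np.ndarray):
    H1 = np.maximum(X @ w["W1"] + w["b1"], 0.0)
    Z = H1 @ w["W2"] + w["b2"]                      # linear bottleneck
    H2 = np.maximum(Z @ w["W3"] + w["b3"], 0.0)
    Y = H2 @ w["W4"] + w["b4"]
    return H1, Z, H2, Y


def _gradients(w: dict, X: np.ndarray) -> tuple[dict, float]:
    H1, Z, H2, Y = _forward(w, X)
    n_cells = X.size
    diff = Y - X
    loss = float(np.mean(diff * diff))
    dY = 2.0 * diff / n_cells
    g = {}
    g["W4"] = H2.T @ dY
    g["b4"] = dY.sum(axis=0)
    dH2 = (dY @ w["W4"].T) * (H2 > 0)
    g["W3"] = Z.T @ dH2
    g["b3"] = dH2.sum(axis=0)
    dZ = dH2 @ w["W3"].T
    g["W2"] = H1.T @ dZ
    g["b2"] = dZ.sum(axis=0)
    dH1 = (dZ @ w["W2"].T) * (H1 > 0)
    g["W1"] = X.T @ dH1
    g["b1"] = dH1.sum(axis=0)
    return g, loss


class _Adam:
    """Standard Adam with bias correction."""

    def __init__(self, weights: dict, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def step(self, weights: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            weights[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps)


@dataclass
class FittedAutoencoder:
    """A trained per-mask autoencoder with its full training trace."""

    spec: EncoderSpec
    weights: dict
    loss_history: list[float]
    mask_name: str = ""
    config: TrainConfig | None = None

    @property
    def final_error(self) -> float:
        return self.loss_history[-1]

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected {self.spec.input_dim} columns, got shape {X.shape}")
        return X

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Bottleneck activations (n x latent_dim)."""
        X = self._check_width(X)
        _, Z, _, _ = _forward(self.weights, X)
        return Z

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        X = self._check_width(X)
        return _forward(self.weights, X)[3]


def train_autoencoder(block: np.ndarray, latent_dim: int,
                      cfg: TrainConfig = TrainConfig(),
                      mask_name: str = "") -> FittedAutoencoder:
    """Train one autoencoder on a standardized, complete feature block.

    The loss history records the full-block MSE at the end of every epoch;
    training stops at ``max_epochs`` or when the loss has not improved by
    ``min_delta`` for ``patience`` consecutive epochs.  Deterministic given
    ``cfg.seed``.
    """
    X = np.asarray(block, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D block, got shape {X.shape}")
    if np.isnan(X).any():
        raise ValueError("block contains missing cells; standardize and "
                         "impute before autoencoder training")
    if X.shape[0] < 2:
        raise ValueError(f"need >= 2 rows to train, got {X.shape[0]}")
    spec = build_autoencoder(X.shape[1], latent_dim)
    rng = np.random.default_rng(cfg.seed)
    weights = _init_weights(spec, rng)
    opt = _Adam(weights, cfg.learning_rate)
    n = X.shape[0]
    batch = max(1, min(cfg.batch_size, n))
    history: list[float] = []
    best = math.inf
    stall = 0
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            grads, _ = _gradients(weights, X[idx])
            opt.step(weights, grads)
        _, _, _, Y = _forward(weights, X)
        loss = float(np.mean((Y - X) ** 2))
        history.append(loss)
        if best - loss > cfg.min_delta:
            best = loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return FittedAutoencoder(spec=spec, weights=weights, loss_history=history,
                             mask_name=mask_name, config=cfg)


def mse(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean over all cells of squared reconstruction residuals."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def reconstruction_error(model: FittedAutoencoder, data: np.ndarray) -> float:
    """Per-cell MSE of the model's reconstruction of ``data``."""
    return mse(data, model.reconstruct(data))


def svd_reconstruction_error(block: np.ndarray, rank: int) -> float:
    """Rank-``rank`` truncated-SVD reconstruction MSE of ``block``.

    The best possible *linear* reconstruction at a given rank — a lower
    bound (up to centering effects) used as the independent oracle for
    autoencoder reconstruction quality.
    """
    X = np.asarray(block, dtype=float)
    s = np.linalg.svd(X, compute_uv=False)
    return float(np.sum(s[rank:] ** 2) / X.size)


@dataclass
class LatentSearchResult:
    """Outcome of the bottleneck-size grid search."""

    curve: dict[int, float]
    selected_d: int
    threshold: float
    met_threshold: bool


def select_latent_size(curve: Mapping[int, float],
                       threshold: float) -> tuple[int, bool]:
    """Smallest d with error below threshold, else argmin (ties -> smaller d)."""
    if not curve:
        raise ValueError("empty search curve")
    qualifying = [d for d in sorted(curve) if curve[d] < threshold]
    if qualifying:
        return qualifying[0], True
    best = min(sorted(curve), key=lambda d: curve[d])
    return best, False


def search_latent_size(block: np.ndarray, candidates: Sequence[int],
                       threshold: float = 0.2,
                       cfg: TrainConfig = TrainConfig()) -> LatentSearchResult:
    """Train one autoencoder per candidate bottleneck size.

    Selection is dimensionality-parsimonious: the smallest candidate whose
    final training error beats the threshold; if none qualifies, the error
    argmin with ``met_threshold=False``.  Each candidate trains with a seed
    derived from ``cfg.seed`` and the candidate size, so the curve is
    reproducible candidate-by-candidate.
    """
    candidates = sorted(int(d) for d in candidates)
    if not candidates:
        raise ValueError("empty candidate range")
    D = np.asarray(block).shape[1]
    if candidates[0] < 1 or candidates[-1] > D:
        raise ValueError(
            f"candidates must lie in [1, {D}]; got range "
            f"[{candidates[0]}, {candidates[-1]}]")
    curve: dict[int, float] = {}
    for d in candidates:
        cfg_d = replace(cfg, seed=derive_seed(cfg.seed, "latent", d))
        model = train_autoencoder(block, d, cfg_d)
        curve[d] = model.final_error
    selected, met = select_latent_size(curve, threshold)
    return LatentSearchResult(curve=curve, selected_d=selected,
                              threshold=threshold, met_threshold=met)


def encode_concat(models: Mapping[str, FittedAutoencoder],
                  blocks: Mapping[str, np.ndarray],
                  mask_order: Sequence[str]) -> np.ndarray:
    """Concatenate per-mask bottleneck encodings in declared mask order.

    Output width is the sum of the latent dimensions (e.g. 4 masks x 15
    latents = 60 columns); rows align with the input samples.
    """
    parts = []
    for mask in mask_order:
        if mask not in models:
            raise ValueError(f"no fitted autoencoder for mask '{mask}'")
        if mask not in blocks:
            raise ValueError(f"no feature block for mask '{mask}'")
        parts.append(models[mask].encode(blocks[mask]))
    return np.hstack(parts)


def encoded_column_names(models: Mapping[str, FittedAutoencoder],
                         mask_order: Sequence[str]) -> list[str]:
    """Column labels of :func:`encode_concat` output, mask-major."""
    names = []
    for mask in mask_order:
        for j in range(models[mask].spec.latent_dim):
            names.append(f"{mask}__z{j}")
    return names


@dataclass
class ManifoldResult:
    coords: np.ndarray
    model: FittedAutoencoder
    figure: object | None = None


def manifold_2d(block: np.ndarray, cfg: TrainConfig = TrainConfig(),
                labels: np.ndarray | None = None,
                out_png: str | None = None, out_csv: str | None = None,
                axis_limit: float = 15.0, title: str = "") -> ManifoldResult:
    """Two-dimensional latent manifold of one feature block.

    Trains a bottleneck-2 autoencoder and returns the n x 2 coordinates.
    When plotting, points are colored by class and the axes are clipped to
    ``[-axis_limit, axis_limit]`` (outlier mappings can exceed the view).
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] < 2:
        raise ValueError("manifold requires a block with >= 2 columns")
    model = train_autoencoder(block, 2, cfg)
    coords = model.encode(block)
    figure = None
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        figure, ax = plt.subplots(figsize=(5, 5))
        if labels is None:
            ax.scatter(coords[:, 0], coords[:, 1], s=12, alpha=0.7)
        else:
            labels = np.asarray(labels)
            palette = {"GBM": "tab:red", "LYM": "tab:green", "MET": "tab:blue"}
            for i, cls in enumerate(dict.fromkeys(labels)):
                sel = labels == cls
                ax.scatter(coords[sel, 0], coords[sel, 1], s=12, alpha=0.7,
                           label=str(cls),
                           color=palette.get(str(cls), f"C{i}"))
            ax.legend(frameon=False, fontsize=8)
        ax.set_xlim(-axis_limit, axis_limit)
        ax.set_ylim(-axis_limit, axis_limit)
        ax.set_xlabel("latent 1")
        ax.set_ylabel("latent 2")
        if title:
            ax.set_title(title)
        figure.tight_layout()
        figure.savefig(out_png, dpi=120)
        plt.close(figure)
    if out_csv is not None:
        np.savetxt(out_csv, coords, delimiter=",", header="z1,z2", comments="")
    return ManifoldResult(coords=coords, model=model, figure=figure)
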