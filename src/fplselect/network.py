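"""The classifier network with its Feature Prune Layer (FPL).

The FPL is a one-to-one elementwise layer prepended to a small fully
connected classifier.  Its output is ``x * W * m`` where ``W`` are trainable
weights initialised to ones and ``m`` is a binary mask that realises
unstructured pruning: pruning never alters ``W`` itself, it only zeroes mask
entries, so the layer stays in the computational graph for the whole
training run.  Because the mask multiplies the forward pass, the gradient of
the loss with respect to a masked weight is exactly zero; Adam moments at
masked positions are additionally zeroed at every step so that masked
weights are bitwise frozen (adaptive optimizers can otherwise move
zero-gradient parameters through stale momentum).

The network is implemented directly in NumPy: the masked-update contract and
bit-reproducibility require full control over initialisation, batching and
optimizer state, and the architectures involved are small.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "FPLState",
    "BaseNetConfig",
    "TrainConfig",
    "TrainTrace",
    "FPLNetwork",
    "AdamOptimizer",
    "fpl_forward",
    "prune_step",
    "train_epochs",
    "train_one_epoch",
    "reduce_network",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class FPLState:
    """Weights, mask and prune-step counter of the Feature Prune Layer."""

    weights: np.ndarray
    mask: np.ndarray
    prune_step_counter: int = 1

    @classmethod
    def initial(cls, d0: int) -> "FPLState":
        return cls(weights=np.ones(d0), mask=np.ones(d0, dtype=int))

    @property
    def d0(self) -> int:
        return self.weights.shape[0]

    @property
    def active_count(self) -> int:
        return int(self.mask.sum())

    @property
    def active_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def copy(self) -> "FPLState":
        return FPLState(self.weights.copy(), self.mask.copy(),
                        self.prune_step_counter)


@dataclass
class BaseNetConfig:
    """Fully connected classifier head: hidden layer sizes + output classes.

    The default (256, 128, 64) with 2 output classes and no dropout is the
    architecture selected by the architecture-comparison protocol.
    """

    hidden_sizes: tuple[int, ...] = (256, 128, 64)
    dropout_prob: float = 0.0
    n_classes: int = 2

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    epochs: int = 70

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainTrace:
    """Per-epoch training record."""

    train_precision: list[float] = field(default_factory=list)
    val_precision: list[float] = field(default_factory=list)
    pseudo_overfitting: list[float] = field(default_factory=list)
    active_count: list[int] = field(default_factory=list)

    def append(self, train_prec: float, val_prec: float, psovft: float,
               active: int) -> None:
        self.train_precision.append(float(train_prec))
        self.val_precision.append(float(val_prec))
        self.pseudo_overfitting.append(float(psovft))
        self.active_count.append(int(active))

    def __len__(self) -> int:
        return len(self.train_precision)

    def to_dict(self) -> dict:
        return asdict(self)


def fpl_forward(x: np.ndarray, state: FPLState) -> np.ndarray:
    """Elementwise FPL semantics: ``out_i = x_i * W_i * m_i``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != state.d0:
        raise ValueError(
            f"input width {x.shape[-1]} != FPL size {state.d0}")
    return x * (state.weights * state.mask)


def prune_step(state: FPLState, n_delete: int) -> FPLState:
    """Zero the mask at the ``n_delete`` active positions of smallest |W|.

    Ties in |W| are broken by lowest column index (stable sort).  Weight
    values themselves are untouched; masked positions never return.
    """
    if n_delete < 1:
        raise ValueError("n_delete must be >= 1")
    active = state.active_indices
    if n_delete > active.size:
        raise ValueError(
            f"cannot prune {n_delete} of {active.size} active weights")
    order = np.argsort(np.abs(state.weights[active]), kind="stable")
    victims = active[order[:n_delete]]
    new = state.copy()
    new.mask[victims] = 0
    new.prune_step_counter += 1
    return new


class FPLNetwork:
    """Small fully connected classifier, optionally fronted by an FPL.

    Hidden layers use ReLU; the output layer produces logits for a softmax
    cross-entropy loss.  Linear layers are initialised with the standard
    uniform fan-in scheme U(-1/sqrt(fan_in), 1/sqrt(fan_in)); FPL weights
    start at one.
    """

    def __init__(self, d0: int, config: BaseNetConfig | None = None,
                 with_fpl: bool = True, seed: int = 0):
        self.d0 = int(d0)
        self.config = config if config is not None else BaseNetConfig()
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        sizes = [self.d0, *self.config.hidden_sizes, self.config.n_classes]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, (fan_in, fan_out)))
            self.biases.append(rng.uniform(-bound, bound, fan_out))
        self.fpl = FPLState.initial(self.d0) if with_fpl else None

    # ---------------------------------------------------------------- forward
    def forward(self, X: np.ndarray, training: bool = False,
                dropout_rng: np.random.Generator | None = None):
        """Return (logits, cache).  Dropout is applied only when training."""
        X = np.asarray(X, dtype=float)
        cache: dict = {"X": X, "h": [], "z": [], "drop": []}
        h = fpl_forward(X, self.fpl) if self.fpl is not None else X
        cache["fpl_out"] = h
        n_layers = len(self.weights)
        p = self.config.dropout_prob
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            cache["h"].append(h)
            z = h @ W + b
            if i < n_layers - 1:
                cache["z"].append(z)
                h = np.maximum(z, 0.0)
                if training and p > 0.0:
                    if dropout_rng is None:
                        raise ValueError("dropout requires a generator")
                    keep = (dropout_rng.random(h.shape) >= p)
                    h = h * keep / (1.0 - p)
                    cache["drop"].append(keep)
                else:
                    cache["drop"].append(None)
            else:
                h = z
        return h, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(X, training=False)
        return np.argmax(logits, axis=1)

    # --------------------------------------------------------------- backward
    @staticmethod
    def loss_and_dlogits(logits: np.ndarray, y: np.ndarray):
        """Mean softmax cross-entropy and its gradient w.r.t. logits."""
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        n = len(y)
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-300))
        d = probs.copy()
        d[np.arange(n), y] -= 1.0
        return loss, d / n

    def backward(self, cache: dict, dlogits: np.ndarray):
        """Gradients for all linear layers and (if present) the FPL weights."""
        gW = [np.empty(0)] * len(self.weights)
        gb = [np.empty(0)] * len(self.biases)
        grad = dlogits
        p = self.config.dropout_prob
        for i in range(len(self.weights) - 1, -1, -1):
            h = cache["h"][i]
            gW[i] = h.T @ grad
            gb[i] = grad.sum(axis=0)
            if i > 0:
                grad = grad @ self.weights[i].T
                keep = cache["drop"][i - 1]
                if keep is not None:
                    grad = grad * keep / (1.0 - p)
                grad = grad * (cache["z"][i - 1] > 0)
        g_fpl = None
        if self.fpl is not None:
            grad_in = grad @ self.weights[0].T  # d loss / d (fpl output)
            # dh0/dW_i carries the mask factor, so masked gradients are 0
            g_fpl = (grad_in * cache["X"] * self.fpl.mask).sum(axis=0)
        return gW, gb, g_fpl

    # ------------------------------------------------------------- parameters
    def parameters(self) -> list[np.ndarray]:
        params = list(self.weights) + list(self.biases)
        if self.fpl is not None:
            params.append(self.fpl.weights)
        return params

    def copy(self) -> "FPLNetwork":
        new = FPLNetwork.__new__(FPLNetwork)
        new.d0 = self.d0
        new.config = self.config
        new.seed = self.seed
        new.weights = [W.copy() for W in self.weights]
        new.biases = [b.copy() for b in self.biases]
        new.fpl = self.fpl.copy() if self.fpl is not None else None
        return new


class AdamOptimizer:
    """Adam with per-parameter moment buffers.

    ``mask_hook`` (set when an FPL is present) zeroes the FPL moments at
    masked positions after every update, guaranteeing that masked weights
    never move.
    """

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray],
             fpl: FPLState | None = None) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t)
                                                + self.eps)
        if fpl is not None:
            # the FPL weight vector is the last parameter; freeze masked slots
            self.m[-1] *= fpl.mask
            self.v[-1] *= fpl.mask

    def zero_masked_moments(self, fpl: FPLState) -> None:
        self.m[-1] *= fpl.mask
        self.v[-1] *= fpl.mask


def make_optimizer(model: FPLNetwork, cfg: TrainConfig) -> AdamOptimizer:
    if cfg.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    return AdamOptimizer(model.parameters(), lr=cfg.learning_rate)


def train_one_epoch(model: FPLNetwork, opt: AdamOptimizer, X: np.ndarray,
                    y: np.ndarray, batch_size: int,
                    rng: np.random.Generator) -> float:
    """One pass of shuffled mini-batch gradient training; returns mean loss."""
    n = len(y)
    order = rng.permutation(n)
    losses = []
    for start in range(0, n, batch_size):
        idx = order[start:start + batch_size]
        logits, cache = model.forward(X[idx], training=True, dropout_rng=rng)
        loss, dlogits = model.loss_and_dlogits(logits, y[idx])
        gW, gb, g_fpl = model.backward(cache, dlogits)
        grads = gW + gb
        if model.fpl is not None:
            grads.append(g_fpl)
        opt.step(grads, fpl=model.fpl)
        losses.append(loss)
    return float(np.mean(losses))


def train_epochs(model: FPLNetwork, X_train: np.ndarray, y_train: np.ndarray,
                 X_val: np.ndarray, y_val: np.ndarray,
                 config: TrainConfig,
                 epochs: int | None = None) -> TrainTrace:
    """Train for a fixed number of epochs recording per-epoch metrics.

    Deterministic given ``config.seed``: batching, dropout and initialisation
    all derive from seeded generators.
    """
    from .evaluation import macro_precision, pseudo_overfitting

    if len(y_train) == 0 or len(y_val) == 0:
        raise ValueError("train/validation splits must be non-empty")
    epochs = config.epochs if epochs is None else epochs
    opt = make_optimizer(model, config)
    rng = np.random.default_rng(config.seed)
    trace = TrainTrace()
    for _ in range(epochs):
        train_one_epoch(model, opt, X_train, y_train, config.batch_size, rng)
        tp = macro_precision(y_train, model.predict(X_train))
        vp = macro_precision(y_val, model.predict(X_val))
        active = model.fpl.active_count if model.fpl is not None else model.d0
        trace.append(tp, vp, pseudo_overfitting(tp, vp), active)
    return trace


def reduce_network(model: FPLNetwork) -> tuple["FPLNetwork", np.ndarray]:
    """Physically remove pruned inputs, folding surviving FPL weights in.

    Returns an FPL-free network over the surviving columns whose first-layer
    rows are the surviving rows of the original first layer scaled by the
    surviving FPL weights, plus the surviving column indices.  Its forward
    pass on column-reduced input equals the masked FPL forward on full input.
    """
    if model.fpl is None:
        raise ValueError("model has no FPL to reduce")
    keep = model.fpl.active_indices
    reduced = FPLNetwork(len(keep), model.config, with_fpl=False,
                         seed=model.seed)
    reduced.weights = [W.copy() for W in model.weights]
    reduced.biases = [b.copy() for b in model.biases]
    w_active = model.fpl.weights[keep]
    reduced.weights[0] = model.weights[0][keep, :] * w_active[:, None]
    return reduced, keep


def save_checkpoint(path, model: FPLNetwork, train_cfg: TrainConfig) -> None:
    """Single-file archive: FPL weights+mask, base weights, configs, seed."""
    arrays = {f"W{i}": W for i, W in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    if model.fpl is not None:
        arrays["fpl_weights"] = model.fpl.weights
        arrays["fpl_mask"] = model.fpl.mask
        arrays["fpl_counter"] = np.array(model.fpl.prune_step_counter)
    meta = {
        "d0": model.d0,
        "with_fpl": model.fpl is not None,
        "net": asdict(model.config),
        "train": asdict(train_cfg),
        "seed": model.seed,
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[FPLNetwork, TrainConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        net_cfg = BaseNetConfig(**{**meta["net"],
                                   "hidden_sizes": tuple(meta["net"]["hidden_sizes"])})
        model = FPLNetwork(meta["d0"], net_cfg, with_fpl=meta["with_fpl"],
                           seed=meta["seed"])
        model.weights = [data[f"W{i}"] for i in range(len(model.weights))]
        model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
        if meta["with_fpl"]:
            model.fpl = FPLState(data["fpl_weights"],
                                 data["fpl_mask"],
                                 int(data["fpl_counter"]))
        train_cfg = TrainConfig(**meta["train"])
    return model, train_cfg
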