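"""The deep-network core for per-residue sequence labeling.

Architecture (per task): each residue is represented by a window of ``w``
positions around it.  Every position contributes the learned embedding
column of its residue symbol and/or the scaled 20-dimensional profile row;
these are concatenated into one feature vector, passed through fully
connected hidden layer(s) with a hard-tanh transfer, then through a
task-specific linear output layer and a softmax, yielding a posterior
distribution over the task's label classes.  Training minimizes the
negative log-likelihood by stochastic gradient descent with analytic
backpropagated gradients, one randomly sampled window per step.

Everything is plain float64 numpy; single-threaded execution with a fixed
seed is bitwise reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabets import PAD_INDEX, SYMBOLS
from .exceptions import ConfigError

logger = logging.getLogger(__name__)

#: Floor applied to posteriors inside the log to keep the loss finite.
POSTERIOR_FLOOR = 1e-12

PROFILE_DIM = 20


@dataclass
class Hyperparams:
    """Training hyperparameters.

    window        odd sliding-window size w (residues)
    embed_dim     embedding dimensionality d
    hidden_units  units per hidden layer
    lr            SGD learning rate (constant; no decay)
    margin        margin of the ranking loss for the natural-protein task
    tol           convergence tolerance on held-out error improvement
    max_iters     cap on training iterations
    updates_per_iter  SGD updates per iteration between validation checks;
                      None means min(total training windows, 100000)
    seed          RNG seed for initialization, splits and sampling
    """

    window: int = 13
    embed_dim: int = 15
    hidden_units: int = 300
    lr: float = 0.005
    margin: float = 1.0
    tol: float = 5e-5
    max_iters: int = 150
    updates_per_iter: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigError(f"window must be odd and >= 1, got {self.window}")
        if self.hidden_units < 1:
            raise ConfigError("hidden_units must be >= 1")
        if self.embed_dim < 1:
            raise ConfigError("embed_dim must be >= 1")
        if self.lr < 0:
            raise ConfigError("learning rate must be >= 0")
        if self.margin <= 0:
            raise ConfigError("margin must be > 0")
        if self.tol <= 0:
            raise ConfigError("tol must be > 0")


@dataclass
class EmbeddingTable:
    """Learnable d x |A| lookup table, one column per dictionary symbol."""

    symbols: tuple[str, ...]
    dim: int
    weights: np.ndarray  # dim x |symbols|

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.dim, len(self.symbols)):
            raise ConfigError(
                f"embedding weights shape {self.weights.shape} != "
                f"({self.dim}, {len(self.symbols)})"
            )

    @classmethod
    def random(cls, dim: int, rng: np.random.Generator,
               symbols: tuple[str, ...] = SYMBOLS) -> "EmbeddingTable":
        """Centered uniform initialization on [-r, r], r = 1/sqrt(d)."""
        if dim < 1:
            raise ConfigError("embedding dimension must be >= 1")
        r = 1.0 / np.sqrt(dim)
        return cls(symbols, dim, rng.uniform(-r, r, size=(dim, len(symbols))))

    def copy(self) -> "EmbeddingTable":
        return EmbeddingTable(self.symbols, self.dim, self.weights.copy())

    def column(self, symbol: str) -> np.ndarray:
        return self.weights[:, self.symbols.index(symbol)]


@dataclass
class WindowExample:
    """One training/prediction example: a w-window centered on a residue."""

    tokens: np.ndarray                    # (w,) dictionary indices
    profile: np.ndarray | None = None     # (w, 20) scaled rows, zeros at padding
    label: int | None = None              # class index, or None
    corrupted_from: int | None = None     # original middle token if corrupted

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        if self.profile is not None:
            self.profile = np.asarray(self.profile, dtype=float)
            if self.profile.shape != (len(self.tokens), PROFILE_DIM):
                raise ConfigError(
                    f"profile slice shape {self.profile.shape} != "
                    f"({len(self.tokens)}, {PROFILE_DIM})"
                )


@dataclass
class Layer:
    W: np.ndarray
    b: np.ndarray


@dataclass
class NetworkParams:
    """All trainable weights: shared layers plus one output layer per task.

    ``hidden`` (and the embedding, when present) are shared across every
    registered task; only the entries of ``task_outputs`` are task-specific.
    """

    embedding: EmbeddingTable | None
    hidden: list[Layer]
    task_outputs: dict[str, Layer]
    window: int
    use_profile: bool
    provenance: dict[str, str] = field(default_factory=dict)
    skipped_steps: int = 0

    @property
    def use_embedding(self) -> bool:
        return self.embedding is not None

    @property
    def feature_dim(self) -> int:
        per_pos = (self.embedding.dim if self.embedding is not None else 0)
        per_pos += PROFILE_DIM if self.use_profile else 0
        return self.window * per_pos

    def task_names(self) -> list[str]:
        return list(self.task_outputs)


def init_params(
    window: int,
    tasks: dict[str, int],
    hidden_units: int | Sequence[int],
    embed_dim: int | None,
    use_profile: bool,
    seed: int | np.random.Generator,
    init_embedding: EmbeddingTable | None = None,
) -> NetworkParams:
    """Initialize all weights i.i.d. uniform on [-r, r] with r = 1/sqrt(fan-in).

    ``embed_dim=None`` builds a profile-only network.  ``init_embedding``
    seeds the lookup table from a previously learned embedding (copied, so
    the donor table is not mutated).  Reproducible given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"window must be odd and >= 1, got {window}")
    if not tasks:
        raise ConfigError("at least one task must be registered")
    if embed_dim is None and not use_profile:
        raise ConfigError("network needs embedding features, profile features or both")

    embedding = None
    if embed_dim is not None:
        if embed_dim < 1:
            raise ConfigError("embed_dim must be >= 1")
        embedding = EmbeddingTable.random(embed_dim, rng)
        if init_embedding is not None:
            if init_embedding.dim != embed_dim:
                raise ConfigError(
                    f"init embedding has d={init_embedding.dim}, expected {embed_dim}"
                )
            if init_embedding.symbols != embedding.symbols:
                raise ConfigError("init embedding dictionary mismatch")
            embedding = init_embedding.copy()

    sizes = [hidden_units] if isinstance(hidden_units, int) else list(hidden_units)
    if not sizes or any(s < 1 for s in sizes):
        raise ConfigError(f"invalid hidden layer sizes {sizes}")

    per_pos = (embed_dim or 0) + (PROFILE_DIM if use_profile else 0)
    fan_in = window * per_pos
    hidden: list[Layer] = []
    for n in sizes:
        r = 1.0 / np.sqrt(fan_in)
        hidden.append(Layer(rng.uniform(-r, r, size=(n, fan_in)),
                            rng.uniform(-r, r, size=n)))
        fan_in = n

    task_outputs: dict[str, Layer] = {}
    for name, n_classes in tasks.items():
        if n_classes < 2:
            raise ConfigError(f"task {name!r} needs >= 2 classes")
        r = 1.0 / np.sqrt(fan_in)
        task_outputs[name] = Layer(rng.uniform(-r, r, size=(n_classes, fan_in)),
                                   rng.uniform(-r, r, size=n_classes))

    return NetworkParams(embedding, hidden, task_outputs, window, use_profile)


# --- feature assembly -------------------------------------------------------


def assemble_features(
    window: WindowExample,
    emb: EmbeddingTable | None,
    use_profile: bool = True,
) -> np.ndarray:
    """Concatenate [embedding column || profile row] across window positions.

    Length is w*(d+20) with both feature types, w*d embedding-only (the
    natural-protein configuration), w*20 profile-only.
    """
    parts = []
    if emb is not None:
        if np.any(window.tokens < 0) or np.any(window.tokens >= len(emb.symbols)):
            raise LookupError("window token outside the residue dictionary")
        parts.append(emb.weights[:, window.tokens].T)  # (w, d)
    if use_profile:
        if window.profile is None:
            raise ConfigError("profile features requested but window has none")
        parts.append(window.profile)
    if not parts:
        raise ConfigError("no feature source selected")
    return np.concatenate(parts, axis=1).ravel()


def batch_features(
    token_windows: np.ndarray,
    profile_windows: np.ndarray | None,
    emb: EmbeddingTable | None,
    use_profile: bool,
) -> np.ndarray:
    """Vectorized assemble_features for an (N, w) batch of token windows."""
    parts = []
    if emb is not None:
        parts.append(np.transpose(emb.weights[:, token_windows], (1, 2, 0)))
    if use_profile:
        if profile_windows is None:
            raise ConfigError("profile features requested but none supplied")
        parts.append(profile_windows)
    block = np.concatenate(parts, axis=2)  # (N, w, per_pos)
    return block.reshape(block.shape[0], -1)


def pad_tokens(token_indices: np.ndarray, window: int) -> np.ndarray:
    """Pad a protein's token-index array with w//2 padding symbols per side."""
    half = window // 2
    return np.concatenate(
        [np.full(half, PAD_INDEX, dtype=np.int64),
         np.asarray(token_indices, dtype=np.int64),
         np.full(half, PAD_INDEX, dtype=np.int64)]
    )


def sliding_windows(padded: np.ndarray, window: int) -> np.ndarray:
    """All length-w windows of a padded index array, shape (L, w)."""
    return np.lib.stride_tricks.sliding_window_view(padded, window).copy()


def pad_profile(scaled: np.ndarray | None, length: int, window: int) -> np.ndarray:
    """Pad a scaled profile with zero rows; synthesizes zeros when absent."""
    half = window // 2
    if scaled is None:
        return np.zeros((length + 2 * half, PROFILE_DIM))
    return np.vstack(
        [np.zeros((half, PROFILE_DIM)), np.asarray(scaled, float),
         np.zeros((half, PROFILE_DIM))]
    )


def profile_windows(padded_profile: np.ndarray, window: int) -> np.ndarray:
    """All (w, 20) profile slices of a zero-padded profile, shape (L, w, 20)."""
    return np.lib.stride_tricks.sliding_window_view(
        padded_profile, (window, PROFILE_DIM)
    )[:, 0]


# --- forward / backward -----------------------------------------------------


def transfer(x: np.ndarray) -> np.ndarray:
    """Hard-tanh: clip to [-1, 1], identity in between."""
    return np.clip(x, -1.0, 1.0)


def _transfer_grad(pre: np.ndarray) -> np.ndarray:
    return ((pre > -1.0) & (pre < 1.0)).astype(float)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_full(features: np.ndarray, params: NetworkParams, task: str):
    """Forward pass keeping intermediates for backpropagation."""
    if task not in params.task_outputs:
        raise LookupError(f"task {task!r} is not registered in this network")
    x = np.asarray(features, dtype=float)
    activations = [x]
    preacts = []
    for layer in params.hidden:
        a = layer.W @ activations[-1] + layer.b
        preacts.append(a)
        activations.append(transfer(a))
    out = params.task_outputs[task]
    z = out.W @ activations[-1] + out.b
    return activations, preacts, z, softmax(z)


def forward(features: np.ndarray, params: NetworkParams, task: str) -> np.ndarray:
    """Posterior distribution over the task's classes for one window."""
    return _forward_full(features, params, task)[3]


def forward_batch(X: np.ndarray, params: NetworkParams, task: str) -> np.ndarray:
    """Posterior rows for a batch of feature vectors (N, F) -> (N, K)."""
    if task not in params.task_outputs:
        raise LookupError(f"task {task!r} is not registered in this network")
    H = np.asarray(X, dtype=float)
    for layer in params.hidden:
        H = transfer(H @ layer.W.T + layer.b)
    out = params.task_outputs[task]
    return softmax(H @ out.W.T + out.b)


def nll_loss(posterior: np.ndarray, label: int) -> float:
    """Negative log-likelihood of the true class under the posterior."""
    p = float(posterior[label])
    if p < POSTERIOR_FLOOR:
        logger.warning("posterior %.3g at the true label clipped to floor", p)
        p = POSTERIOR_FLOOR
    return -float(np.log(p))


@dataclass
class Gradients:
    """Gradient structure mirroring NetworkParams (drawn task only)."""

    embedding: np.ndarray | None
    hidden: list[Layer]
    task_outputs: dict[str, Layer]
    features: np.ndarray


def backward(
    example: WindowExample | np.ndarray,
    params: NetworkParams,
    task: str,
    label: int,
) -> Gradients:
    """Exact analytic gradients of nll_loss w.r.t. every parameter.

    Accepts a WindowExample (embedding-column gradients are scattered onto
    the window's tokens) or a raw feature vector (embedding gradient None).
    """
    if isinstance(example, WindowExample):
        features = assemble_features(example, params.embedding, params.use_profile)
        tokens = example.tokens
    else:
        features = np.asarray(example, dtype=float)
        tokens = None

    activations, preacts, _, probs = _forward_full(features, params, task)
    dz = probs.copy()
    dz[label] -= 1.0  # d NLL / d output pre-activation

    out = params.task_outputs[task]
    g_out = Layer(np.outer(dz, activations[-1]), dz.copy())
    dh = out.W.T @ dz

    g_hidden: list[Layer] = [None] * len(params.hidden)  # type: ignore[list-item]
    for i in range(len(params.hidden) - 1, -1, -1):
        da = dh * _transfer_grad(preacts[i])
        g_hidden[i] = Layer(np.outer(da, activations[i]), da)
        dh = params.hidden[i].W.T @ da
    dx = dh

    g_emb = None
    if tokens is not None and params.embedding is not None:
        d = params.embedding.dim
        per_pos = d + (PROFILE_DIM if params.use_profile else 0)
        g_emb = np.zeros_like(params.embedding.weights)
        blocks = dx.reshape(params.window, per_pos)[:, :d]
        np.add.at(g_emb.T, tokens, blocks)
    return Gradients(g_emb, g_hidden, {task: g_out}, dx)


def sgd_step(
    params: NetworkParams,
    example: WindowExample,
    task: str,
    lr: float,
) -> NetworkParams:
    """One in-place SGD update on a labeled window.

    Non-finite gradients skip the step and increment params.skipped_steps.
    """
    if example.label is None:
        raise ConfigError("sgd_step requires a labeled example")
    grads = backward(example, params, task, example.label)
    finite = np.isfinite(grads.features).all() and all(
        np.isfinite(g.W).all() and np.isfinite(g.b).all() for g in grads.hidden
    )
    g_out = grads.task_outputs[task]
    finite = finite and np.isfinite(g_out.W).all() and np.isfinite(g_out.b).all()
    if not finite:
        params.skipped_steps += 1
        logger.warning("non-finite gradient; SGD step skipped")
        return params
    out = params.task_outputs[task]
    out.W -= lr * g_out.W
    out.b -= lr * g_out.b
    for layer, g in zip(params.hidden, grads.hidden):
        layer.W -= lr * g.W
        layer.b -= lr * g.b
    if grads.embedding is not None:
        params.embedding.weights -= lr * grads.embedding
    return params


def gradient_check(
    params: NetworkParams,
    example: WindowExample,
    task: str,
    eps: float = 1e-6,
) -> float:
    """Max relative deviation of analytic gradients from central differences.

    The numeric side only ever calls the forward pass and the loss, so it is
    independent of the backpropagation code it audits.  Relative deviation
    is |analytic - numeric| / max(1, |analytic|, |numeric|).
    """
    if example.label is None:
        raise ConfigError("gradient_check needs a labeled example")
    label = example.label

    def loss() -> float:
        feats = assemble_features(example, params.embedding, params.use_profile)
        return nll_loss(forward(feats, params, task), label)

    grads = analytic = backward(example, params, task, label)

    def numeric(array: np.ndarray, idx: tuple) -> float:
        orig = array[idx]
        array[idx] = orig + eps
        up = loss()
        array[idx] = orig - eps
        down = loss()
        array[idx] = orig
        return (up - down) / (2 * eps)

    worst = 0.0

    def compare(param_arr: np.ndarray, grad_arr: np.ndarray) -> None:
        nonlocal worst
        for idx in np.ndindex(param_arr.shape):
            a = float(grad_arr[idx])
            n = numeric(param_arr, idx)
            worst = max(worst, abs(a - n) / max(1.0, abs(a), abs(n)))

    if params.embedding is not None:
        # only columns the window touches can carry gradient; checking all
        # columns also verifies the untouched ones stay exactly zero
        compare(params.embedding.weights, analytic.embedding)
    for layer, g in zip(params.hidden, grads.hidden):
        compare(layer.W, g.W)
        compare(layer.b, g.b)
    out = params.task_outputs[task]
    g_out = grads.task_outputs[task]
    compare(out.W, g_out.W)
    compare(out.b, g_out.b)
    return worst


# --- checkpoints -------------------------------------------------------------

CHECKPOINT_FORMAT = "protlabel-checkpoint-v1"


def save_checkpoint(params: NetworkParams, path: str | Path,
                    metadata: dict | None = None) -> None:
    """Save a network to a single .npz container.

    The container holds every weight array at full precision plus a JSON
    metadata entry recording the residue dictionary, the architecture
    (window, feature flags, layer sizes), the task registry and any
    caller-supplied training metadata.  save -> load -> forward is exact.
    """
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "format": CHECKPOINT_FORMAT,
        "window": params.window,
        "use_profile": params.use_profile,
        "n_hidden": len(params.hidden),
        "tasks": {t: int(l.W.shape[0]) for t, l in params.task_outputs.items()},
        "provenance": params.provenance,
        "metadata": metadata or {},
    }
    if params.embedding is not None:
        meta["embedding"] = {
            "symbols": "".join(params.embedding.symbols),
            "dim": params.embedding.dim,
        }
        arrays["embedding"] = params.embedding.weights
    for i, layer in enumerate(params.hidden):
        arrays[f"hidden_{i}_W"] = layer.W
        arrays[f"hidden_{i}_b"] = layer.b
    for t, layer in params.task_outputs.items():
        arrays[f"task_{t}_W"] = layer.W
        arrays[f"task_{t}_b"] = layer.b
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[NetworkParams, dict]:
    """Load a checkpoint saved by save_checkpoint; returns (params, metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ConfigError(f"{path}: not a {CHECKPOINT_FORMAT} file")
        embedding = None
        if "embedding" in meta:
            embedding = EmbeddingTable(
                tuple(meta["embedding"]["symbols"]),
                int(meta["embedding"]["dim"]),
                data["embedding"].copy(),
            )
        hidden = [
            Layer(data[f"hidden_{i}_W"].copy(), data[f"hidden_{i}_b"].copy())
            for i in range(meta["n_hidden"])
        ]
        task_outputs = {
            t: Layer(data[f"task_{t}_W"].copy(), data[f"task_{t}_b"].copy())
            for t in meta["tasks"]
        }
    params = NetworkParams(
        embedding, hidden, task_outputs, meta["window"], meta["use_profile"],
        provenance=dict(meta.get("provenance", {})),
    )
    return params, meta.get("metadata", {})
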