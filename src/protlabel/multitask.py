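"""Single-task and multitask training loops.

Multitask training shares the embedding table and hidden layer(s) across all
registered tasks; only each task's output layer is task-specific.  Training
interleaves stochastic updates: draw a task uniformly at random, draw one of
its labeled windows, take one SGD step.  Tasks with much larger training
sets ("large" tasks) can be pre-trained jointly before the full multitask
phase so they reach a stable region of parameter space first.

One *iteration* is a fixed budget of SGD updates (default: the total number
of labeled training windows, capped at 100 000) followed by a held-out
validation evaluation.  Training stops when the held-out per-residue error
improves by less than the tolerance (default 0.00005) or at the iteration
cap (default 150).  One fifth of each task's proteins is held out for
validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabets import encode_labels, encode_sequence
from .exceptions import ConfigError
from .io_formats import LabelSequence, ProfileMatrix, ProteinRecord, blosum62_profile
from .network import (
    EmbeddingTable,
    Hyperparams,
    Layer,
    NetworkParams,
    batch_features,
    forward_batch,
    init_params,
    pad_profile,
    pad_tokens,
    sliding_windows,
    softmax,
    transfer,
    _transfer_grad,
)

logger = logging.getLogger(__name__)

#: Cap on SGD updates per iteration when updates_per_iter is unset.
MAX_UPDATES_PER_ITER = 100_000

#: Tasks the pre-training stage trains jointly before full multitasking.
LARGE_TASKS = ("ss", "dssp", "saa", "sar")


@dataclass
class LabeledProtein:
    """One dataset entry: sequence, aligned labels, optional profile."""

    record: ProteinRecord
    labels: LabelSequence
    profile: ProfileMatrix | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.record):
            raise ConfigError(
                f"{self.record.id}: {len(self.labels)} labels vs "
                f"{len(self.record)} residues"
            )


@dataclass
class TaskSpec:
    """A labeling task: alphabet, dataset, CV fold assignment, size class."""

    name: str
    alphabet: tuple[str, ...]
    dataset: list[LabeledProtein]
    folds: list[int] = field(default_factory=list)
    large: bool = False

    def __post_init__(self) -> None:
        self.alphabet = tuple(self.alphabet)
        if len(self.alphabet) < 2:
            raise ConfigError(f"task {self.name!r}: alphabet needs >= 2 labels")
        if not self.folds:
            self.folds = [0] * len(self.dataset)
        if len(self.folds) != len(self.dataset):
            raise ConfigError(f"task {self.name!r}: folds do not cover the dataset")

    @property
    def n_classes(self) -> int:
        return len(self.alphabet)

    def protein_indices(self, fold: int | None = None, exclude: bool = False) -> list[int]:
        """Indices of proteins in (or excluding) one CV fold; all when None."""
        if fold is None:
            return list(range(len(self.dataset)))
        if exclude:
            return [i for i, f in enumerate(self.folds) if f != fold]
        return [i for i, f in enumerate(self.folds) if f == fold]


@dataclass
class TrainingHistory:
    """Held-out error per iteration plus why and when training stopped."""

    errors: list[float] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def iterations(self) -> int:
        return len(self.errors)


def split_validation(
    task: TaskSpec, seed: int | np.random.Generator,
    pool: Sequence[int] | None = None,
) -> tuple[list[int], list[int]]:
    """Protein-level 80/20 train/validation split, reproducible by seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = list(pool) if pool is not None else list(range(len(task.dataset)))
    if len(pool) < 5:
        raise ConfigError(
            f"task {task.name!r}: need >= 5 proteins to hold out one fifth, "
            f"got {len(pool)}"
        )
    perm = rng.permutation(len(pool))
    n_val = len(pool) // 5
    val = sorted(pool[i] for i in perm[:n_val])
    train = sorted(pool[i] for i in perm[n_val:])
    return train, val


def check_convergence(
    history: TrainingHistory, tol: float, max_iters: int = 150
) -> bool:
    """True iff the latest error improvement is below tol or the cap is hit."""
    if history.iterations >= max_iters:
        return True
    if history.iterations < 2:
        return False
    return (history.errors[-2] - history.errors[-1]) < tol


# --- compiled task state ------------------------------------------------------


class TaskSampler:
    """Training-ready view of one task: padded arrays and a window sampler."""

    def __init__(
        self,
        task: TaskSpec,
        window: int,
        use_profile: bool,
        train_proteins: Sequence[int],
        val_proteins: Sequence[int],
    ):
        self.name = task.name
        self.alphabet = task.alphabet
        self.n_classes = task.n_classes
        self.window = window
        self.use_profile = use_profile
        self.half = window // 2

        self._tokens: list[np.ndarray] = []
        self._profiles: list[np.ndarray | None] = []
        self._labels: list[np.ndarray] = []
        for item in task.dataset:
            self._tokens.append(pad_tokens(encode_sequence(item.record.sequence), window))
            if use_profile:
                profile = item.profile or blosum62_profile(item.record)
                self._profiles.append(pad_profile(profile.scaled, len(item.record), window))
            else:
                self._profiles.append(None)
            self._labels.append(encode_labels(item.labels.labels, task.alphabet))

        prot, pos, lab = [], [], []
        for p in train_proteins:
            labeled = np.nonzero(self._labels[p] >= 0)[0]
            prot.append(np.full(len(labeled), p, dtype=np.int64))
            pos.append(labeled)
            lab.append(self._labels[p][labeled])
        self.ex_protein = np.concatenate(prot) if prot else np.empty(0, np.int64)
        self.ex_pos = np.concatenate(pos) if pos else np.empty(0, np.int64)
        self.ex_label = np.concatenate(lab) if lab else np.empty(0, np.int64)
        self.n_train = len(self.ex_label)
        self.val_proteins = list(val_proteins)
        if self.n_train == 0:
            logger.warning("task %r has no labeled training windows", self.name)

    def example(self, i: int) -> tuple[np.ndarray, np.ndarray | None, int]:
        """Token window, profile slice and label of training example i."""
        p, pos = self.ex_protein[i], self.ex_pos[i]
        tok = self._tokens[p][pos:pos + self.window]
        prof = None
        if self.use_profile:
            prof = self._profiles[p][pos:pos + self.window]
        return tok, prof, int(self.ex_label[i])

    def protein_features(self, p: int, params: NetworkParams) -> np.ndarray:
        """Feature matrix (L, F) for every position of protein p."""
        tok = sliding_windows(self._tokens[p], self.window)
        prof = None
        if self.use_profile:
            prof = np.lib.stride_tricks.sliding_window_view(
                self._profiles[p], (self.window, 20)
            )[:, 0]
        return batch_features(tok, prof, params.embedding, self.use_profile)

    def validation_error(self, params: NetworkParams) -> float:
        """Per-residue error rate over the held-out proteins."""
        wrong = total = 0
        for p in self.val_proteins:
            labels = self._labels[p]
            mask = labels >= 0
            if not mask.any():
                continue
            probs = forward_batch(self.protein_features(p, params), params, self.name)
            pred = probs.argmax(axis=1)
            wrong += int((pred[mask] != labels[mask]).sum())
            total += int(mask.sum())
        if total == 0:
            raise ConfigError(f"task {self.name!r}: no labeled validation positions")
        return wrong / total

    def training_q_score(self, params: NetworkParams) -> float:
        """Per-residue accuracy over the training windows themselves."""
        correct = 0
        for p in sorted(set(self.ex_protein.tolist())):
            sel = self.ex_protein == p
            probs = forward_batch(self.protein_features(p, params), params, self.name)
            pred = probs.argmax(axis=1)
            correct += int((pred[self.ex_pos[sel]] == self.ex_label[sel]).sum())
        return correct / self.n_train


def _train_step(
    params: NetworkParams,
    tok: np.ndarray,
    prof: np.ndarray | None,
    task: str,
    label: int,
    lr: float,
) -> None:
    """Fused forward/backward/update for one window (hot path)."""
    emb = params.embedding
    if emb is not None:
        E = emb.weights[:, tok].T
        x = np.concatenate([E, prof], axis=1).ravel() if prof is not None else E.ravel()
    else:
        x = prof.ravel()

    activations = [x]
    preacts = []
    for layer in params.hidden:
        a = layer.W @ activations[-1] + layer.b
        preacts.append(a)
        activations.append(transfer(a))
    out = params.task_outputs[task]
    probs = softmax(out.W @ activations[-1] + out.b)

    dz = probs
    dz[label] -= 1.0
    dh = out.W.T @ dz
    out.W -= lr * np.outer(dz, activations[-1])
    out.b -= lr * dz
    for i in range(len(params.hidden) - 1, -1, -1):
        da = dh * _transfer_grad(preacts[i])
        if i > 0 or emb is not None:
            dh = params.hidden[i].W.T @ da
        params.hidden[i].W -= lr * np.outer(da, activations[i])
        params.hidden[i].b -= lr * da
    if emb is not None:
        d = emb.dim
        per_pos = d + (20 if prof is not None else 0)
        blocks = dh.reshape(params.window, per_pos)[:, :d]
        np.add.at(emb.weights.T, tok, -lr * blocks)


def interleaved_step(
    samplers: Sequence[TaskSampler],
    params: NetworkParams,
    rng: np.random.Generator,
    lr: float,
) -> tuple[NetworkParams, str]:
    """One multitask SGD update: uniform task draw, then one window of it.

    Shared layers move on every draw; only the drawn task's output layer
    changes.  Tasks without training windows are excluded from sampling.
    Returns the (in-place updated) params and the drawn task's name.
    """
    eligible = [s for s in samplers if s.n_train > 0]
    if not eligible:
        raise ConfigError("no task has labeled training windows")
    sampler = eligible[rng.integers(len(eligible))] if len(eligible) > 1 else eligible[0]
    tok, prof, label = sampler.example(int(rng.integers(sampler.n_train)))
    _train_step(params, tok, prof, sampler.name, label, lr)
    return params, sampler.name


def _run_training(
    params: NetworkParams,
    samplers: list[TaskSampler],
    hyper: Hyperparams,
    rng: np.random.Generator,
) -> dict[str, TrainingHistory]:
    """Interleaved SGD until the mean held-out error converges.

    Returns one history per task plus the aggregate history under the key
    'mean' (for a single task the two coincide).
    """
    eligible = [s for s in samplers if s.n_train > 0]
    if not eligible:
        raise ConfigError("no task has labeled training windows")
    total = sum(s.n_train for s in eligible)
    updates = hyper.updates_per_iter or min(total, MAX_UPDATES_PER_ITER)

    histories = {s.name: TrainingHistory() for s in samplers}
    mean_history = TrainingHistory()
    n = len(eligible)
    while True:
        for _ in range(updates):
            s = eligible[rng.integers(n)] if n > 1 else eligible[0]
            tok, prof, label = s.example(int(rng.integers(s.n_train)))
            _train_step(params, tok, prof, s.name, label, hyper.lr)
        errs = []
        for s in samplers:
            e = s.validation_error(params)
            histories[s.name].errors.append(e)
            errs.append(e)
        mean_history.errors.append(float(np.mean(errs)))
        if check_convergence(mean_history, hyper.tol, hyper.max_iters):
            reason = ("max_iters" if mean_history.iterations >= hyper.max_iters
                      else "converged")
            mean_history.stop_reason = reason
            for h in histories.values():
                h.stop_reason = reason
            break
    histories["mean"] = mean_history
    return histories


def _make_samplers(
    tasks: Sequence[TaskSpec],
    hyper: Hyperparams,
    use_profile: bool,
    rng: np.random.Generator,
    protein_indices: dict[str, Sequence[int]] | None,
) -> list[TaskSampler]:
    samplers = []
    for task in tasks:
        pool = None if protein_indices is None else protein_indices.get(task.name)
        train_idx, val_idx = split_validation(task, rng, pool)
        samplers.append(TaskSampler(task, hyper.window, use_profile, train_idx, val_idx))
    return samplers


def train_single(
    task: TaskSpec,
    hyper: Hyperparams,
    use_embedding: bool = True,
    use_profile: bool = True,
    init_embedding: EmbeddingTable | None = None,
    protein_indices: Sequence[int] | None = None,
) -> tuple[NetworkParams, TrainingHistory]:
    """Train one task on its own network until convergence.

    ``use_embedding=False`` gives the profile-only feature vector (w*20);
    ``init_embedding`` starts the lookup table from a previously learned
    embedding (e.g. from the natural-protein task).
    """
    rng = np.random.default_rng(hyper.seed)
    params = init_params(
        hyper.window, {task.name: task.n_classes}, hyper.hidden_units,
        hyper.embed_dim if use_embedding else None, use_profile, rng,
        init_embedding=init_embedding,
    )
    indices = None if protein_indices is None else {task.name: protein_indices}
    samplers = _make_samplers([task], hyper, use_profile, rng, indices)
    histories = _run_training(params, samplers, hyper, rng)
    return params, histories[task.name]


def pretrain_large(
    tasks: Sequence[TaskSpec],
    hyper: Hyperparams,
    use_embedding: bool = True,
    use_profile: bool = True,
    init_embedding: EmbeddingTable | None = None,
    protein_indices: dict[str, Sequence[int]] | None = None,
) -> NetworkParams:
    """Jointly train the large-flagged tasks; the result seeds the full run.

    Output layers exist for every task in *tasks*, but only the large tasks
    are trained here; the others are freshly re-initialized by
    train_multitask when the full phase starts (provenance-tagged).
    """
    large = [t for t in tasks if t.large]
    if not large:
        raise ConfigError("pretrain_large: no task is flagged large")
    rng = np.random.default_rng(hyper.seed)
    params = init_params(
        hyper.window, {t.name: t.n_classes for t in tasks}, hyper.hidden_units,
        hyper.embed_dim if use_embedding else None, use_profile, rng,
        init_embedding=init_embedding,
    )
    samplers = _make_samplers(large, hyper, use_profile, rng, protein_indices)
    _run_training(params, samplers, hyper, rng)
    for t in tasks:
        params.provenance[t.name] = "pretrained" if t.large else "fresh"
    return params


def train_multitask(
    tasks: Sequence[TaskSpec],
    hyper: Hyperparams,
    pretrain: bool = False,
    use_embedding: bool = True,
    use_profile: bool = True,
    init_embedding: EmbeddingTable | None = None,
    protein_indices: dict[str, Sequence[int]] | None = None,
) -> tuple[NetworkParams, dict[str, TrainingHistory]]:
    """Interleaved multitask training with equal task weights.

    Every task contributes its negative log-likelihood with equal weight;
    sampling is uniform over tasks.  With ``pretrain=True`` the large tasks
    are trained jointly first, non-large output layers are freshly
    re-initialized, and the full interleaved phase follows.  Convergence is
    judged on the unweighted mean of per-task held-out errors.
    """
    names = [t.name for t in tasks]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate task names in {names}")
    if len(tasks) < 2:
        raise ConfigError("train_multitask needs >= 2 tasks")
    rng = np.random.default_rng(hyper.seed)
    if pretrain:
        params = pretrain_large(
            tasks, hyper, use_embedding, use_profile, init_embedding,
            protein_indices,
        )
        # reset the never-trained output layers so the full phase starts
        # them from scratch while the shared layers keep the pretrained state
        fan_in = params.hidden[-1].W.shape[0]
        r = 1.0 / np.sqrt(fan_in)
        for t in tasks:
            if not t.large:
                layer = params.task_outputs[t.name]
                layer.W[:] = rng.uniform(-r, r, size=layer.W.shape)
                layer.b[:] = rng.uniform(-r, r, size=layer.b.shape)
    else:
        params = init_params(
            hyper.window, {t.name: t.n_classes for t in tasks}, hyper.hidden_units,
            hyper.embed_dim if use_embedding else None, use_profile, rng,
            init_embedding=init_embedding,
        )
    samplers = _make_samplers(tasks, hyper, use_profile, rng, protein_indices)
    histories = _run_training(params, samplers, hyper, rng)
    return params, histories
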