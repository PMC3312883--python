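"""Model/Results facades tying the training, decoding and metric layers together.

``ProteinLabelingModel`` is built from one or more labeling tasks plus
hyperparameters; ``fit()`` runs the appropriate training loop and returns a
``LabelingResults`` carrying the trained weights, per-task training
histories, estimated label-transition models and evaluation helpers.
``NaturalProteinModel`` does the same for the self-supervised ranking task,
returning the learned amino-acid embedding.

The named training regimes mirror the standard experimental comparisons:

========== ============ =========== ========= =====================
regime     multitask    embedding   profile   embedding init
========== ============ =========== ========= =====================
single     no           no          yes       --
embed      no           yes         yes       random
np         no           yes         yes       natural-protein task
np-only    no           yes         no        natural-protein task
multi      yes          no          yes       --
multi-emb  yes          yes         yes       random
all3       yes          yes         yes       natural-protein task
all3-vit   as all3, plus Viterbi post-processing at prediction time
========== ============ =========== ========= =====================
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .decode import TransitionModel, estimate_transitions, predict_labels
from .exceptions import ConfigError
from .io_formats import (
    LabelSequence,
    ProfileMatrix,
    ProteinRecord,
    load_config,
    read_fasta,
    read_labels,
    read_pssm,
)
from .metrics import EvalReport, evaluate_task, knn_overlap
from .multitask import (
    LabeledProtein,
    TaskSpec,
    TrainingHistory,
    train_multitask,
    train_single,
)
from .natural import export_embedding, train_natural
from .network import (
    EmbeddingTable,
    Hyperparams,
    NetworkParams,
    load_checkpoint,
    save_checkpoint,
)

#: Regime name -> (multitask, use_embedding, use_profile, needs_init, viterbi)
REGIMES: dict[str, tuple[bool, bool, bool, bool, bool]] = {
    "single": (False, False, True, False, False),
    "embed": (False, True, True, False, False),
    "np": (False, True, True, True, False),
    "np-only": (False, True, False, True, False),
    "multi": (True, False, True, False, False),
    "multi-emb": (True, True, True, False, False),
    "all3": (True, True, True, True, False),
    "all3-vit": (True, True, True, True, True),
}


class ProteinLabelingModel:
    """A per-residue labeling network over one or several tasks."""

    def __init__(
        self,
        tasks: Sequence[TaskSpec] | TaskSpec,
        hyper: Hyperparams | None = None,
        *,
        multitask: bool | None = None,
        use_embedding: bool = True,
        use_profile: bool = True,
        init_embedding: EmbeddingTable | None = None,
        pretrain: bool = False,
        viterbi: bool = False,
        transition_pseudocount: float = 1.0,
    ):
        self.tasks = [tasks] if isinstance(tasks, TaskSpec) else list(tasks)
        if not self.tasks:
            raise ConfigError("at least one task is required")
        self.hyper = hyper or Hyperparams()
        self.multitask = len(self.tasks) > 1 if multitask is None else multitask
        if self.multitask and len(self.tasks) < 2:
            raise ConfigError("multitask training needs >= 2 tasks")
        if not self.multitask and len(self.tasks) > 1:
            raise ConfigError("single-task training got several tasks")
        self.use_embedding = use_embedding
        self.use_profile = use_profile
        self.init_embedding = init_embedding
        self.pretrain = pretrain
        self.viterbi = viterbi
        self.transition_pseudocount = transition_pseudocount

    @classmethod
    def from_regime(
        cls,
        regime: str,
        tasks: Sequence[TaskSpec] | TaskSpec,
        hyper: Hyperparams | None = None,
        init_embedding: EmbeddingTable | None = None,
        pretrain: bool = False,
    ) -> "ProteinLabelingModel":
        if regime not in REGIMES:
            raise ConfigError(f"unknown regime {regime!r}; one of {sorted(REGIMES)}")
        multitask, use_emb, use_prof, needs_init, viterbi = REGIMES[regime]
        if needs_init and init_embedding is None:
            raise ConfigError(f"regime {regime!r} requires a pre-trained embedding")
        return cls(
            tasks, hyper, multitask=multitask, use_embedding=use_emb,
            use_profile=use_prof, init_embedding=init_embedding,
            pretrain=pretrain, viterbi=viterbi,
        )

    def fit(
        self, seed: int | None = None, test_fold: int | None = None
    ) -> "LabelingResults":
        """Train until convergence; optionally hold one CV fold out entirely."""
        hyper = self.hyper
        if seed is not None:
            hyper = dataclasses.replace(hyper, seed=seed)
        indices = None
        if test_fold is not None:
            indices = {
                t.name: t.protein_indices(test_fold, exclude=True) for t in self.tasks
            }
        if self.multitask:
            params, histories = train_multitask(
                self.tasks, hyper, pretrain=self.pretrain,
                use_embedding=self.use_embedding, use_profile=self.use_profile,
                init_embedding=self.init_embedding, protein_indices=indices,
            )
        else:
            task = self.tasks[0]
            pool = None if indices is None else indices[task.name]
            params, history = train_single(
                task, hyper, use_embedding=self.use_embedding,
                use_profile=self.use_profile, init_embedding=self.init_embedding,
                protein_indices=pool,
            )
            histories = {task.name: history, "mean": history}
        transitions = {}
        for t in self.tasks:
            pool = range(len(t.dataset)) if indices is None else indices[t.name]
            transitions[t.name] = estimate_transitions(
                [t.dataset[i].labels for i in pool], t.alphabet,
                self.transition_pseudocount,
            )
        return LabelingResults(self, params, histories, transitions, test_fold)


class LabelingResults:
    """Fitted weights plus training diagnostics and evaluation helpers."""

    def __init__(
        self,
        model: ProteinLabelingModel,
        params: NetworkParams,
        histories: dict[str, TrainingHistory],
        transitions: dict[str, TransitionModel],
        test_fold: int | None = None,
    ):
        self.model = model
        self.params = params
        self.histories = histories
        self.transitions = transitions
        self.test_fold = test_fold
        self.alphabets = {t.name: t.alphabet for t in model.tasks}

    def _task(self, task: str | None) -> TaskSpec:
        if task is None:
            if len(self.model.tasks) > 1:
                raise ConfigError("several tasks fitted; name one")
            return self.model.tasks[0]
        for t in self.model.tasks:
            if t.name == task:
                return t
        raise ConfigError(f"task {task!r} was not fitted")

    def predict(
        self,
        protein: ProteinRecord,
        profile: ProfileMatrix | None = None,
        task: str | None = None,
        viterbi: bool | None = None,
    ) -> tuple[LabelSequence, np.ndarray]:
        """Predicted labeling and posterior matrix for one protein."""
        t = self._task(task)
        use_vit = self.model.viterbi if viterbi is None else viterbi
        return predict_labels(
            self.params, protein, profile, t.name, t.alphabet,
            viterbi=use_vit, transitions=self.transitions.get(t.name),
        )

    def evaluate(
        self,
        task: str | None = None,
        fold: int | None = None,
        viterbi: bool | None = None,
    ) -> EvalReport:
        """Score the task's proteins (optionally one CV fold) end to end."""
        t = self._task(task)
        fold = self.test_fold if fold is None else fold
        idx = t.protein_indices(fold)
        if not idx:
            raise ConfigError(f"task {t.name!r}: no proteins in fold {fold}")
        pairs = []
        for i in idx:
            item = t.dataset[i]
            pred, _ = self.predict(item.record, item.profile, t.name, viterbi)
            pairs.append((pred, item.labels))
        return evaluate_task(pairs, t.alphabet, t.name)

    def summary(self) -> str:
        """Human-readable per-task training summary table."""
        rows = []
        for t in self.model.tasks:
            h = self.histories[t.name]
            rows.append({
                "task": t.name,
                "classes": t.n_classes,
                "proteins": len(t.dataset),
                "iterations": h.iterations,
                "stop": h.stop_reason,
                "held-out error": h.errors[-1] if h.errors else float("nan"),
            })
        frame = pd.DataFrame(rows)
        head = "ProteinLabelingModel results"
        mode = "multitask" if self.model.multitask else "single-task"
        feats = "+".join(
            n for n, on in (("embedding", self.model.use_embedding),
                            ("profile", self.model.use_profile)) if on
        )
        return f"{head} ({mode}, features: {feats})\n{frame.to_string(index=False)}"

    def save(self, path: str | Path) -> None:
        """Write a reloadable checkpoint (weights + alphabets + transitions)."""
        meta = {
            "alphabets": {k: "".join(v) for k, v in self.alphabets.items()},
            "transitions": {
                k: {
                    "alphabet": "".join(tm.alphabet),
                    "log_init": tm.log_init.tolist(),
                    "log_trans": tm.log_trans.tolist(),
                }
                for k, tm in self.transitions.items()
            },
            "histories": {
                k: {"errors": h.errors, "stop_reason": h.stop_reason}
                for k, h in self.histories.items()
            },
            "test_fold": self.test_fold,
            "viterbi": self.model.viterbi,
        }
        save_checkpoint(self.params, path, meta)


def load_results(path: str | Path) -> "LoadedResults":
    """Reload a checkpoint for prediction/evaluation without the datasets."""
    params, meta = load_checkpoint(path)
    transitions = {
        k: TransitionModel(
            tuple(v["alphabet"]), np.array(v["log_init"]), np.array(v["log_trans"])
        )
        for k, v in meta.get("transitions", {}).items()
    }
    alphabets = {k: tuple(v) for k, v in meta.get("alphabets", {}).items()}
    return LoadedResults(params, alphabets, transitions, meta)


class LoadedResults:
    """Prediction-only view of a saved checkpoint."""

    def __init__(self, params, alphabets, transitions, meta):
        self.params = params
        self.alphabets = alphabets
        self.transitions = transitions
        self.meta = meta

    def predict(
        self,
        protein: ProteinRecord,
        profile: ProfileMatrix | None = None,
        task: str | None = None,
        viterbi: bool = False,
    ) -> tuple[LabelSequence, np.ndarray]:
        if task is None:
            names = list(self.alphabets)
            if len(names) != 1:
                raise ConfigError(f"checkpoint holds tasks {names}; name one")
            task = names[0]
        if task not in self.alphabets:
            raise ConfigError(f"task {task!r} not in checkpoint")
        return predict_labels(
            self.params, protein, profile, task, self.alphabets[task],
            viterbi=viterbi, transitions=self.transitions.get(task),
        )


class NaturalProteinModel:
    """The self-supervised ranking model over an unlabeled corpus."""

    def __init__(self, corpus: Sequence[ProteinRecord], hyper: Hyperparams | None = None):
        self.corpus = list(corpus)
        self.hyper = hyper or Hyperparams()

    def fit(self, seed: int | None = None) -> "NaturalResults":
        hyper = self.hyper
        if seed is not None:
            hyper = dataclasses.replace(hyper, seed=seed)
        embedding, net, history = train_natural(self.corpus, hyper)
        return NaturalResults(self, embedding, net, history)


class NaturalResults:
    """Learned embedding plus the scoring network and training history."""

    def __init__(self, model, embedding: EmbeddingTable, net, history):
        self.model = model
        self.embedding = embedding
        self.net = net
        self.history = history

    def score_windows(self, token_windows: np.ndarray) -> np.ndarray:
        return self.net.score_batch(token_windows)

    def export(self, path: str | Path) -> None:
        export_embedding(self.embedding, path)

    def knn_overlap_with(self, matrix: np.ndarray, k: int) -> float:
        return knn_overlap(self.embedding, matrix, k)

    def summary(self) -> str:
        h = self.history
        return (
            "NaturalProteinModel results\n"
            f"corpus sequences: {len(self.model.corpus)}\n"
            f"embedding dim: {self.embedding.dim}\n"
            f"iterations: {h.iterations} ({h.stop_reason})\n"
            f"held-out ranking loss: {h.errors[-1]:.4f}"
        )


def tasks_from_config(cfg: dict, base_dir: str | Path = ".") -> list[TaskSpec]:
    """Build TaskSpecs from a configuration mapping (paths relative to base)."""
    base = Path(base_dir)
    tasks = []
    for entry in cfg.get("tasks", []):
        records = read_fasta(base / entry["fasta"])
        alphabet = tuple(entry["alphabet"])
        labels = read_labels(
            base / entry["labels"], alphabet, {r.id: r.sequence for r in records}
        )
        dataset = []
        for rec in records:
            if rec.id not in labels:
                raise ConfigError(f"no labels for protein {rec.id!r}")
            profile = None
            if entry.get("pssm_dir"):
                pssm = base / entry["pssm_dir"] / f"{rec.id}.pssm"
                if pssm.exists():
                    profile = read_pssm(pssm, len(rec))
            dataset.append(LabeledProtein(rec, labels[rec.id], profile))
        tasks.append(
            TaskSpec(
                entry["name"], alphabet, dataset,
                list(entry.get("folds", [])), bool(entry.get("large", False)),
            )
        )
    if not tasks:
        raise ConfigError("configuration defines no tasks")
    return tasks


def hyper_from_config(cfg: dict) -> Hyperparams:
    return Hyperparams(**cfg.get("hyper", {}))
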