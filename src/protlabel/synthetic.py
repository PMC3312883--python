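"""Synthetic fixtures with known ground truth.

Three generators give every other module testable inputs without downloads:

* ``generate_multitask_fixture`` — a family of correlated labeling tasks.
  Each protein carries a hidden first-order Markov state path; residues are
  emitted from state-specific residue groups and every task's labels are a
  deterministic recoding of the same hidden path (optionally corrupted at a
  known noise rate).  Because all tasks share the hidden path, their labels
  are mutually informative, which is exactly the regime where multitask
  weight sharing should help.

* ``generate_natural_corpus`` — unlabeled sequences over an alphabet with
  known exchangeable residue groups: the group sequence follows a Markov
  chain and the letter within each group is uniform, so same-group letters
  are statistically interchangeable.  The natural-protein task should place
  them close together in embedding space.

* ``generate_pssm`` — plausible profile matrices whose log-odds peak on the
  emitting residue group, with bounded integer noise.

Everything is deterministic given the seed, and fixtures are written to
standard FASTA/label/PSSM files so they flow through the public I/O path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabets import AMINO_ACIDS
from .exceptions import ConfigError
from .io_formats import (
    LabelSequence,
    ProfileMatrix,
    ProteinRecord,
    write_fasta,
    write_labels,
    write_pssm,
)
from .multitask import LabeledProtein, TaskSpec

#: Label letters available to fixture tasks.
_TASK_LETTERS = "ABCDEFGHIJ"


@dataclass
class FixtureConfig:
    """Knobs of the synthetic generators (all deterministic given seed)."""

    n_proteins: int = 200
    length_range: tuple[int, int] = (50, 150)
    n_tasks: int = 2
    n_states: int = 4
    stay_prob: float = 0.7          # self-transition of the hidden chain
    noise: float = 0.0              # per-position label corruption rate
    share_proteins: bool = False    # all tasks label every protein?
    n_folds: int = 5
    n_groups: int = 4               # exchangeable groups in the natural corpus
    pssm_signal: int = 5            # log-odds boost on the emitting group
    pssm_noise: int = 1             # +- integer noise on every entry
    with_profiles: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.noise < 0.5):
            raise ConfigError("noise rate must lie in [0, 0.5)")
        if self.n_states < 2 or self.n_states > len(_TASK_LETTERS):
            raise ConfigError("n_states must be in [2, 10]")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ConfigError("invalid length range")
        if not (0 < self.stay_prob < 1):
            raise ConfigError("stay_prob must be in (0, 1)")
        if 20 % self.n_groups:
            raise ConfigError("n_groups must divide 20")


def partition_letters(n_parts: int) -> list[str]:
    """Partition the 20 canonical letters into n contiguous groups."""
    if 20 % n_parts:
        # uneven split: distribute the remainder over the first groups
        sizes = [20 // n_parts + (1 if i < 20 % n_parts else 0) for i in range(n_parts)]
    else:
        sizes = [20 // n_parts] * n_parts
    groups, start = [], 0
    for s in sizes:
        groups.append(AMINO_ACIDS[start:start + s])
        start += s
    return groups


def _markov_path(
    n: int, k: int, stay: float, rng: np.random.Generator,
    base: np.ndarray | None = None,
) -> np.ndarray:
    """Sticky Markov chain: leave-state moves draw from *base* (uniform default)."""
    base = np.full(k, 1.0 / k) if base is None else np.asarray(base, float)
    base = base / base.sum()
    probs = stay * np.eye(k) + (1.0 - stay) * base[None, :]
    probs /= probs.sum(axis=1, keepdims=True)
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(k, p=base)
    for t in range(1, n):
        states[t] = rng.choice(k, p=probs[states[t - 1]])
    return states


def generate_multitask_fixture(cfg: FixtureConfig) -> list[TaskSpec]:
    """Correlated labeling tasks driven by a shared hidden state path.

    Each task's labels are an injective recoding (a per-task permutation of
    the label letters) of the protein's hidden states, independently
    corrupted at ``cfg.noise`` (corruption resamples uniformly among the
    other labels).  Proteins are split round-robin across tasks unless
    ``share_proteins`` is set; CV folds are assigned round-robin.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = partition_letters(cfg.n_states)
    alphabet = tuple(_TASK_LETTERS[: cfg.n_states])
    recodings = [rng.permutation(cfg.n_states) for _ in range(cfg.n_tasks)]

    proteins: list[tuple[ProteinRecord, np.ndarray]] = []
    for i in range(cfg.n_proteins):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        states = _markov_path(length, cfg.n_states, cfg.stay_prob, rng)
        seq = "".join(groups[s][rng.integers(len(groups[s]))] for s in states)
        proteins.append((ProteinRecord(f"prot{i:04d}", seq), states))

    tasks: list[TaskSpec] = []
    for t in range(cfg.n_tasks):
        if cfg.share_proteins:
            members = list(range(cfg.n_proteins))
        else:
            members = list(range(t, cfg.n_proteins, cfg.n_tasks))
        dataset, folds = [], []
        for rank, idx in enumerate(members):
            record, states = proteins[idx]
            labels = np.array([recodings[t][s] for s in states])
            if cfg.noise > 0:
                flip = rng.random(len(labels)) < cfg.noise
                shift = rng.integers(1, cfg.n_states, size=len(labels))
                labels = np.where(flip, (labels + shift) % cfg.n_states, labels)
            label_str = "".join(alphabet[v] for v in labels)
            profile = generate_pssm(record, cfg, rng) if cfg.with_profiles else None
            dataset.append(
                LabeledProtein(record, LabelSequence(record.id, label_str), profile)
            )
            folds.append(rank % cfg.n_folds)
        tasks.append(TaskSpec(f"task{t}", alphabet, dataset, folds, large=(t == 0)))
    return tasks


def generate_pssm(
    record: ProteinRecord, cfg: FixtureConfig,
    rng: np.random.Generator | None = None,
) -> ProfileMatrix:
    """Plausible profile: log-odds peaked on the residue's group plus noise."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    groups = partition_letters(cfg.n_states)
    letter_group = {a: g for g, letters in enumerate(groups) for a in letters}
    L = len(record)
    raw = rng.integers(-cfg.pssm_noise, cfg.pssm_noise + 1, size=(L, 20))
    for i, res in enumerate(record.sequence):
        g = letter_group.get(res)
        if g is None:
            continue
        for a in groups[g]:
            raw[i, AMINO_ACIDS.index(a)] += cfg.pssm_signal
    return ProfileMatrix(raw)


def generate_natural_corpus(
    cfg: FixtureConfig,
) -> tuple[list[ProteinRecord], list[str]]:
    """Unlabeled corpus with exchangeable residue groups.

    The group of each position follows a first-order Markov chain
    (self-transition ``stay_prob``); the letter within the group is uniform,
    so letters of one group are exchangeable under the generator.  Group
    usage is deliberately non-uniform (linearly decreasing weights), the way
    residue frequencies in real sequence databases are non-uniform.  Returns
    the records and the ground-truth groups for embedding-recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = partition_letters(cfg.n_groups)
    base = np.arange(cfg.n_groups, 0, -1, dtype=float)  # e.g. 4:3:2:1
    records = []
    for i in range(cfg.n_proteins):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        path = _markov_path(length, cfg.n_groups, cfg.stay_prob, rng, base)
        seq = "".join(groups[g][rng.integers(len(groups[g]))] for g in path)
        records.append(ProteinRecord(f"nat{i:04d}", seq))
    return records, groups


HEPTAD = "abcdefg"


def generate_heptad_task(
    n_proteins: int = 60,
    seed: int = 0,
    coil_residues: str = "ILVMF",
    n_folds: int = 5,
) -> TaskSpec:
    """Coiled-coil-style fixture with a strict heptad label grammar.

    Sequences alternate non-coil stretches (label 'N', any residue) with
    coiled segments whose length is a multiple of 7, labeled with repeating
    ``abcdefg``; the hydrophobic a/d register positions draw from
    ``coil_residues``.  Viterbi decoding with transitions estimated from
    these labels can repair register errors in noisy posteriors.
    """
    rng = np.random.default_rng(seed)
    dataset, folds = [], []
    for i in range(n_proteins):
        seq_parts, lab_parts = [], []
        for block in range(int(rng.integers(2, 5))):
            n_len = int(rng.integers(5, 16))
            seq_parts.append(
                "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=n_len))
            )
            lab_parts.append("N" * n_len)
            reps = int(rng.integers(1, 4))
            coil = []
            for r in range(reps):
                for k, reg in enumerate(HEPTAD):
                    if reg in "ad":
                        coil.append(coil_residues[rng.integers(len(coil_residues))])
                    else:
                        coil.append(AMINO_ACIDS[rng.integers(20)])
            seq_parts.append("".join(coil))
            lab_parts.append(HEPTAD * reps)
        tail = int(rng.integers(5, 16))
        seq_parts.append("".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=tail)))
        lab_parts.append("N" * tail)
        record = ProteinRecord(f"cc{i:04d}", "".join(seq_parts))
        dataset.append(
            LabeledProtein(record, LabelSequence(record.id, "".join(lab_parts)))
        )
        folds.append(i % n_folds)
    return TaskSpec("cc", tuple("N" + HEPTAD), dataset, folds)


def write_fixture(
    tasks: Sequence[TaskSpec],
    out_dir: str | Path,
    corpus: Sequence[ProteinRecord] | None = None,
    groups: Sequence[str] | None = None,
) -> dict:
    """Write a fixture as FASTA + label + PSSM files with a manifest.

    The manifest (fixture_manifest.json) lists every written file with its
    sha256 checksum plus the task alphabets and fold assignments.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tasks": {}, "files": {}}

    def register(path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = hashlib.sha256(
            path.read_bytes()
        ).hexdigest()

    for task in tasks:
        fasta = out / f"{task.name}.fasta"
        labels = out / f"{task.name}.labels"
        write_fasta([d.record for d in task.dataset], fasta)
        write_labels([d.labels for d in task.dataset], labels)
        register(fasta)
        register(labels)
        pssm_dir = None
        if any(d.profile is not None for d in task.dataset):
            pssm_dir = out / f"{task.name}_pssm"
            pssm_dir.mkdir(exist_ok=True)
            for d in task.dataset:
                if d.profile is not None:
                    p = pssm_dir / f"{d.record.id}.pssm"
                    write_pssm(d.record, d.profile, p)
                    register(p)
        manifest["tasks"][task.name] = {
            "alphabet": "".join(task.alphabet),
            "folds": task.folds,
            "large": task.large,
            "fasta": fasta.name,
            "labels": labels.name,
            "pssm_dir": pssm_dir.name if pssm_dir else None,
        }
    if corpus is not None:
        cpath = out / "corpus.fasta"
        write_fasta(corpus, cpath)
        register(cpath)
        manifest["corpus"] = cpath.name
    if groups is not None:
        manifest["groups"] = list(groups)
    with open(out / "fixture_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_fixture(fixture_dir: str | Path) -> list[TaskSpec]:
    """Reload a written fixture through the public I/O path."""
    from .io_formats import read_fasta, read_labels, read_pssm

    d = Path(fixture_dir)
    with open(d / "fixture_manifest.json") as fh:
        manifest = json.load(fh)
    tasks = []
    for name, info in manifest["tasks"].items():
        records = read_fasta(d / info["fasta"])
        alphabet = tuple(info["alphabet"])
        labels = read_labels(
            d / info["labels"], alphabet,
            {r.id: r.sequence for r in records},
        )
        dataset = []
        for rec in records:
            profile = None
            if info["pssm_dir"]:
                profile = read_pssm(d / info["pssm_dir"] / f"{rec.id}.pssm", len(rec))
            dataset.append(LabeledProtein(rec, labels[rec.id], profile))
        tasks.append(TaskSpec(name, alphabet, dataset, info["folds"], info["large"]))
    return tasks
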