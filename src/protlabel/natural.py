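"""The semi-supervised "natural protein" task.

A scoring network (embedding lookup -> window concatenation -> hidden layer
-> single scalar output, no profile features, no softmax) is trained to rank
genuine sequence windows above corrupted ones, where a corrupted window has
its middle residue replaced by a residue drawn uniformly from the 20-letter
dictionary.  The loss per pair is the margin ranking cost
``max(0, margin - score(real) + score(corrupted))``.  The deliverable of
training is not the classifier but the learned amino-acid embedding, which
can initialize the lookup table of the supervised networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .alphabets import AMINO_ACIDS, SYMBOL_INDEX, SYMBOLS, encode_sequence
from .exceptions import ConfigError, DataError
from .io_formats import ProteinRecord
from .network import (
    EmbeddingTable,
    Hyperparams,
    Layer,
    WindowExample,
    _transfer_grad,
    pad_tokens,
    sliding_windows,
    transfer,
)
from .multitask import TrainingHistory

logger = logging.getLogger(__name__)

#: Number of substitutable letters for corruption (the 20 canonical residues).
N_CANONICAL = len(AMINO_ACIDS)


@dataclass
class RankingPair:
    """A genuine window and its middle-corrupted counterpart."""

    positive: WindowExample
    negative: WindowExample


def window_corpus(
    sequences: Iterable[ProteinRecord], w: int
) -> Iterator[WindowExample]:
    """Stream every length-w window (boundary-padded) of every sequence."""
    if w < 1 or w % 2 == 0:
        raise ConfigError(f"window must be odd and >= 1, got {w}")
    for rec in sequences:
        padded = pad_tokens(encode_sequence(rec.sequence), w)
        for pos in range(len(rec)):
            yield WindowExample(padded[pos:pos + w].copy())


def corrupt_window(window: WindowExample, rng: np.random.Generator) -> WindowExample:
    """Replace the middle residue with a uniform draw from the 20 letters.

    Flanks are untouched; the replacement may coincide with the original
    (such pairs contribute margin-level loss and act as regularizers).
    """
    w = len(window.tokens)
    mid = w // 2
    tokens = window.tokens.copy()
    original = int(tokens[mid])
    tokens[mid] = int(rng.integers(N_CANONICAL))
    return WindowExample(tokens, profile=None, corrupted_from=original)


def ranking_loss(score_pos: float, score_neg: float, margin: float) -> float:
    """Margin ranking cost max(0, margin - score_pos + score_neg)."""
    return max(0.0, margin - float(score_pos) + float(score_neg))


class _ScoringNet:
    """Embedding -> hidden (hard-tanh) -> scalar linear output."""

    def __init__(self, emb: EmbeddingTable, window: int, hidden_units: int,
                 rng: np.random.Generator):
        self.emb = emb
        self.window = window
        fan_in = window * emb.dim
        r = 1.0 / np.sqrt(fan_in)
        self.h = Layer(rng.uniform(-r, r, size=(hidden_units, fan_in)),
                       rng.uniform(-r, r, size=hidden_units))
        r = 1.0 / np.sqrt(hidden_units)
        self.out = Layer(rng.uniform(-r, r, size=(1, hidden_units)),
                         rng.uniform(-r, r, size=1))

    def score(self, tokens: np.ndarray) -> float:
        x = self.emb.weights[:, tokens].T.ravel()
        h = transfer(self.h.W @ x + self.h.b)
        return float((self.out.W @ h + self.out.b)[0])

    def score_batch(self, token_windows: np.ndarray) -> np.ndarray:
        X = np.transpose(self.emb.weights[:, token_windows], (1, 2, 0))
        X = X.reshape(X.shape[0], -1)
        H = transfer(X @ self.h.W.T + self.h.b)
        return (H @ self.out.W.T + self.out.b).ravel()

    def _backprop(self, tokens: np.ndarray, dscore: float, lr: float) -> None:
        """One score-gradient step: params -= lr * dscore * d score/d params."""
        x = self.emb.weights[:, tokens].T.ravel()
        a = self.h.W @ x + self.h.b
        h = transfer(a)
        dh = (dscore * self.out.W[0]) * _transfer_grad(a)
        dx = self.h.W.T @ dh
        self.out.W[0] -= lr * dscore * h
        self.out.b -= lr * dscore
        self.h.W -= lr * np.outer(dh, x)
        self.h.b -= lr * dh
        blocks = dx.reshape(self.window, self.emb.dim)
        np.add.at(self.emb.weights.T, tokens, -lr * blocks)

    def pair_step(self, pos_tokens: np.ndarray, neg_tokens: np.ndarray,
                  margin: float, lr: float) -> float:
        s_pos = self.score(pos_tokens)
        s_neg = self.score(neg_tokens)
        loss = ranking_loss(s_pos, s_neg, margin)
        if loss > 0.0:
            self._backprop(pos_tokens, -1.0, lr)
            self._backprop(neg_tokens, +1.0, lr)
        return loss


def _corpus_windows(records: Sequence[ProteinRecord], w: int) -> np.ndarray:
    """Materialize all token windows of a corpus as an (N, w) array."""
    rows = []
    for rec in records:
        padded = pad_tokens(encode_sequence(rec.sequence), w)
        rows.append(sliding_windows(padded, w))
    return np.concatenate(rows, axis=0)


def train_natural(
    corpus: Sequence[ProteinRecord],
    hyper: Hyperparams,
    init_embedding: EmbeddingTable | None = None,
) -> tuple[EmbeddingTable, _ScoringNet, TrainingHistory]:
    """Train the ranking network on a sequence corpus.

    The corpus is split 70/30 into training and validation sequences; the
    held-out mean ranking loss (on freshly corrupted pairs) drives the usual
    convergence rule.  Returns the learned embedding table, the scoring
    network and the training history.
    """
    corpus = list(corpus)
    if not corpus:
        raise DataError("empty corpus")
    rng = np.random.default_rng(hyper.seed)
    emb = (init_embedding.copy() if init_embedding is not None
           else EmbeddingTable.random(hyper.embed_dim, rng))
    net = _ScoringNet(emb, hyper.window, hyper.hidden_units, rng)

    perm = rng.permutation(len(corpus))
    n_train = max(1, int(round(0.7 * len(corpus))))
    train_windows = _corpus_windows([corpus[i] for i in perm[:n_train]], hyper.window)
    val_records = [corpus[i] for i in perm[n_train:]]
    val_windows = (_corpus_windows(val_records, hyper.window)
                   if val_records else train_windows)

    n = len(train_windows)
    updates = hyper.updates_per_iter or min(n, 100_000)
    mid = hyper.window // 2
    # the held-out negatives are corrupted once so successive evaluations
    # are comparable and the improvement-based stopping rule is meaningful
    val_neg = val_windows.copy()
    val_neg[:, mid] = rng.integers(N_CANONICAL, size=len(val_neg))
    history = TrainingHistory()
    while True:
        for _ in range(updates):
            pos_tokens = train_windows[rng.integers(n)]
            neg_tokens = pos_tokens.copy()
            neg_tokens[mid] = rng.integers(N_CANONICAL)
            net.pair_step(pos_tokens, neg_tokens, hyper.margin, hyper.lr)
        losses = np.maximum(
            0.0,
            hyper.margin - net.score_batch(val_windows) + net.score_batch(val_neg),
        )
        history.errors.append(float(losses.mean()))
        # held-out mean ranking loss plays the role of the validation error
        if history.iterations >= hyper.max_iters:
            history.stop_reason = "max_iters"
            break
        if history.iterations >= 2 and (
            history.errors[-2] - history.errors[-1]
        ) < hyper.tol:
            history.stop_reason = "converged"
            break
    return emb, net, history


# --- embedding export / import ----------------------------------------------

_EMBEDDING_HEADER = "# protlabel amino-acid embedding v1"


def export_embedding(table: EmbeddingTable, path: str | Path) -> None:
    """Write an embedding as plain text; round-trips bitwise.

    Layout: a header line, a ``symbols`` line with the dictionary in column
    order, a ``dim`` line, then one row per symbol with repr-formatted
    float64 components (repr round-trips exactly in Python).
    """
    with open(path, "w") as fh:
        fh.write(_EMBEDDING_HEADER + "\n")
        fh.write("symbols\t" + "".join(table.symbols) + "\n")
        fh.write(f"dim\t{table.dim}\n")
        for j, sym in enumerate(table.symbols):
            vals = "\t".join(repr(float(v)) for v in table.weights[:, j])
            fh.write(f"{sym}\t{vals}\n")


def import_embedding(path: str | Path,
                     symbols: tuple[str, ...] = SYMBOLS) -> EmbeddingTable:
    """Read an embedding written by export_embedding.

    The file's dictionary must match the model dictionary exactly (same
    symbols, same column order) or a config error is raised.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _EMBEDDING_HEADER:
        raise ConfigError(f"{path}: not a protlabel embedding file")
    head = dict(ln.split("\t", 1) for ln in lines[1:3])
    file_symbols = tuple(head["symbols"])
    dim = int(head["dim"])
    if file_symbols != tuple(symbols):
        raise ConfigError(
            f"{path}: embedding dictionary {''.join(file_symbols)!r} does not "
            f"match the model dictionary {''.join(symbols)!r}"
        )
    weights = np.empty((dim, len(file_symbols)))
    for ln in lines[3:]:
        if not ln:
            continue
        parts = ln.split("\t")
        sym, vals = parts[0], parts[1:]
        if sym not in SYMBOL_INDEX and sym not in file_symbols:
            raise ConfigError(f"{path}: unknown symbol row {sym!r}")
        j = file_symbols.index(sym)
        if len(vals) != dim:
            raise ConfigError(f"{path}: row {sym!r} has {len(vals)} values, expected {dim}")
        weights[:, j] = [float(v) for v in vals]
    return EmbeddingTable(file_symbols, dim, weights)
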