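"""Viterbi post-processing of per-residue posteriors.

The network labels each residue independently, which ignores strong local
label dependencies (the strict abcdefg register of coiled coils, the
minimum lengths of membrane-spanning helices, ...).  A dynamic-programming
pass repairs this: a bigram label-transition model, estimated from the
training-fold labelings with a pseudocount, is combined in log space with
the per-residue log posteriors, and the highest-scoring label path is
returned.

All scores live in log space; forbidden transitions are encoded with a
large negative sentinel (NEG_INF = -1e30) rather than -inf, so arithmetic
stays finite while any path through a forbidden bigram loses to any path
that avoids one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alphabets import UNLABELED, encode_sequence
from .exceptions import AlignmentError, ConfigError, DataError
from .io_formats import LabelSequence, ProfileMatrix, ProteinRecord
from .network import (
    NetworkParams,
    batch_features,
    forward_batch,
    pad_profile,
    pad_tokens,
    sliding_windows,
)

logger = logging.getLogger(__name__)

#: Log-score sentinel for forbidden transitions (documented: -1e30).
NEG_INF = -1e30


@dataclass
class TransitionModel:
    """Bigram label model: initial log probabilities and a K x K log matrix."""

    alphabet: tuple[str, ...]
    log_init: np.ndarray
    log_trans: np.ndarray

    def __post_init__(self) -> None:
        K = len(self.alphabet)
        self.log_init = np.asarray(self.log_init, dtype=float)
        self.log_trans = np.asarray(self.log_trans, dtype=float)
        if self.log_init.shape != (K,) or self.log_trans.shape != (K, K):
            raise ConfigError("transition model dimensions do not match alphabet")

    @classmethod
    def uniform(cls, alphabet: Sequence[str]) -> "TransitionModel":
        K = len(alphabet)
        return cls(tuple(alphabet), np.full(K, -np.log(K)),
                   np.full((K, K), -np.log(K)))


def _log_normalize(counts: np.ndarray) -> np.ndarray:
    """Row-normalize 2-D counts to log probabilities; empty rows -> uniform."""
    counts = np.atleast_2d(counts).astype(float)
    out = np.empty_like(counts)
    K = counts.shape[1]
    for i, row in enumerate(counts):
        total = row.sum()
        if total == 0:
            out[i] = -np.log(K)
        else:
            with np.errstate(divide="ignore"):
                logp = np.log(row) - np.log(total)
            out[i] = np.where(row > 0, logp, NEG_INF)
    return out


def estimate_transitions(
    labelings: Sequence[LabelSequence | str],
    alphabet: Sequence[str],
    pseudocount: float = 1.0,
) -> TransitionModel:
    """Add-pseudocount bigram ML estimates from training labelings.

    Unlabeled positions are skipped and bigrams spanning a '.' are not
    counted; the initial distribution comes from first-position labels with
    the same pseudocount.  Rows with no data become uniform.
    """
    if not labelings:
        raise DataError("estimate_transitions: no labelings given")
    alphabet = tuple(alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    K = len(alphabet)
    trans = np.full((K, K), float(pseudocount))
    init = np.full(K, float(pseudocount))
    for lab in labelings:
        labels = lab.labels if isinstance(lab, LabelSequence) else lab
        prev = None
        first_seen = False
        for c in labels:
            if c == UNLABELED:
                prev = None
                continue
            if c not in index:
                raise DataError(f"label {c!r} not in alphabet {alphabet}")
            j = index[c]
            if not first_seen:
                init[j] += 1.0
                first_seen = True
            if prev is not None:
                trans[prev, j] += 1.0
            prev = j
    log_trans = _log_normalize(trans)
    log_init = _log_normalize(init)[0]
    return TransitionModel(alphabet, log_init, log_trans)


def viterbi_decode(
    posteriors: np.ndarray, tm: TransitionModel, protein_id: str = ""
) -> LabelSequence:
    """Highest-scoring label path under posteriors + bigram transitions.

    Maximizes sum_t log posterior(t, y_t) + log init(y_1) +
    sum_{t>1} log trans(y_{t-1}, y_t).  Ties break toward the lower label
    index.  If every path is forbidden, falls back to the per-position
    argmax with a warning.
    """
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(tm.alphabet):
        raise ConfigError(
            f"posterior width {P.shape} does not match alphabet size "
            f"{len(tm.alphabet)}"
        )
    L, K = P.shape
    if L < 1:
        raise ConfigError("empty posterior matrix")
    with np.errstate(divide="ignore"):
        logP = np.where(P > 0, np.log(np.maximum(P, 1e-300)), NEG_INF)

    score = tm.log_init + logP[0]
    back = np.zeros((L, K), dtype=np.int64)
    for t in range(1, L):
        cand = score[:, None] + tm.log_trans  # (from, to)
        best_from = cand.argmax(axis=0)       # argmax returns lowest index on ties
        back[t] = best_from
        score = cand[best_from, np.arange(K)] + logP[t]

    if score.max() <= NEG_INF / 2:  # every surviving path hit a sentinel
        logger.warning("%s: all label paths forbidden; per-position argmax", protein_id)
        path = P.argmax(axis=1)
    else:
        path = np.empty(L, dtype=np.int64)
        path[-1] = int(score.argmax())
        for t in range(L - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
    labels = "".join(tm.alphabet[i] for i in path)
    return LabelSequence(protein_id, labels)


def path_score(
    labels: str, posteriors: np.ndarray, tm: TransitionModel
) -> float:
    """Log score of one explicit label path under the decoding model."""
    idx = [tm.alphabet.index(c) for c in labels]
    P = np.asarray(posteriors, dtype=float)
    with np.errstate(divide="ignore"):
        logP = np.where(P > 0, np.log(np.maximum(P, 1e-300)), NEG_INF)
    s = tm.log_init[idx[0]] + logP[0, idx[0]]
    for t in range(1, len(idx)):
        s += tm.log_trans[idx[t - 1], idx[t]] + logP[t, idx[t]]
    return float(s)


def protein_posteriors(
    params: NetworkParams,
    record: ProteinRecord,
    profile: ProfileMatrix | None,
    task: str,
) -> np.ndarray:
    """Per-residue posterior rows (L x K) for one protein."""
    tokens = pad_tokens(encode_sequence(record.sequence), params.window)
    tok_windows = sliding_windows(tokens, params.window)
    prof_windows = None
    if params.use_profile:
        if profile is None:
            from .io_formats import blosum62_profile

            profile = blosum62_profile(record)
        if len(profile) != len(record):
            raise AlignmentError(
                f"{record.id}: profile rows {len(profile)} != sequence "
                f"length {len(record)}"
            )
        padded = pad_profile(profile.scaled, len(record), params.window)
        prof_windows = np.lib.stride_tricks.sliding_window_view(
            padded, (params.window, 20)
        )[:, 0]
    X = batch_features(tok_windows, prof_windows, params.embedding, params.use_profile)
    return forward_batch(X, params, task)


def predict_labels(
    params: NetworkParams,
    protein: ProteinRecord,
    profile: ProfileMatrix | None,
    task: str,
    alphabet: Sequence[str],
    viterbi: bool = False,
    transitions: TransitionModel | None = None,
) -> tuple[LabelSequence, np.ndarray]:
    """End-to-end prediction for one protein.

    Without Viterbi the label is the per-position argmax (for a binary task
    this is the universal 0.5 posterior cutoff); with Viterbi the bigram
    transition model re-scores whole label paths.
    """
    alphabet = tuple(alphabet)
    posteriors = protein_posteriors(params, protein, profile, task)
    if posteriors.shape[1] != len(alphabet):
        raise ConfigError(
            f"task {task!r} has {posteriors.shape[1]} classes, alphabet has "
            f"{len(alphabet)}"
        )
    if viterbi:
        tm = transitions if transitions is not None else TransitionModel.uniform(alphabet)
        labels = viterbi_decode(posteriors, tm, protein.id)
    else:
        path = posteriors.argmax(axis=1)
        labels = LabelSequence(protein.id, "".join(alphabet[i] for i in path))
    return labels, posteriors
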