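"""Evaluation metrics for per-residue labeling tasks.

Covers the per-residue Q-score (accuracy over labeled positions), one-vs-rest
precision/recall/F1 per class, the segment-level transmembrane rule (a
predicted membrane segment is correct iff it overlaps a true membrane
segment by at least five residues; inside/outside/signal segments need a
single residue of overlap), the protein-level signal-peptide rule (a protein
has a predicted signal peptide iff any residue is labeled 'S'), the
coiled-coil percent-correct rule (any heptad letter matches any heptad
letter, 'N' matches only 'N'), a two-proportion pooled Z-test for comparing
accuracies, and the k-nearest-neighbor overlap between a learned amino-acid
embedding and a substitution matrix such as BLOSUM62.

Unlabeled positions ('.') in the true labeling are excluded from every
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import norm

from .alphabets import AMINO_ACIDS, UNLABELED
from .exceptions import ConfigError, DataError
from .io_formats import LabelSequence
from .network import EmbeddingTable

logger = logging.getLogger(__name__)


def _load_blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20), dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = int(mat[a, b])
    return out


#: BLOSUM62 scores over the 20 canonical residues (alphabetical order),
#: taken from Biopython's substitution-matrix collection.
BLOSUM62: np.ndarray = _load_blosum62()


def _labels(x: LabelSequence | str) -> str:
    return x.labels if isinstance(x, LabelSequence) else x


@dataclass
class SegmentSpan:
    """A maximal constant-label run, 1-based inclusive bounds."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigError(f"segment start {self.start} > end {self.end}")

    def overlap(self, other: "SegmentSpan") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class EvalReport:
    """Scores for one task: Q-score, per-class PRF, task-specific extras."""

    q_score: float
    per_class: dict[str, dict[str, float]]
    extras: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "q_score": self.q_score,
            "per_class": self.per_class,
            "extras": self.extras,
        }

    def to_tsv(self) -> str:
        """Flat TSV rendering: one metric per line (metric, class, value)."""
        lines = [f"q_score\t\t{self.q_score!r}"]
        for cls, stats in self.per_class.items():
            for name, value in stats.items():
                lines.append(f"{name}\t{cls}\t{value!r}")
        for name, value in self.extras.items():
            lines.append(f"{name}\t\t{value!r}")
        return "\n".join(lines) + "\n"


def _paired(pred, true):
    p, t = _labels(pred), _labels(true)
    if len(p) != len(t):
        raise DataError(f"labelings differ in length: {len(p)} vs {len(t)}")
    return p, t


def q_score(pred: LabelSequence | str, true: LabelSequence | str) -> float:
    """Fraction of labeled residues predicted correctly."""
    p, t = _paired(pred, true)
    correct = labeled = 0
    for a, b in zip(p, t):
        if b == UNLABELED:
            continue
        labeled += 1
        correct += a == b
    if labeled == 0:
        raise DataError("q_score undefined: no labeled positions")
    return correct / labeled


def per_class_prf(
    pred: LabelSequence | str, true: LabelSequence | str, cls: str,
    alphabet: Sequence[str] | None = None,
) -> tuple[float, float, float]:
    """One-vs-rest precision, recall and F1 for one class.

    Zero denominators yield 0.0 (flagged with a log message).
    """
    if alphabet is not None and cls not in alphabet:
        raise DataError(f"class {cls!r} not in alphabet {tuple(alphabet)}")
    p, t = _paired(pred, true)
    tp = fp = fn = 0
    for a, b in zip(p, t):
        if b == UNLABELED:
            continue
        if a == cls and b == cls:
            tp += 1
        elif a == cls:
            fp += 1
        elif b == cls:
            fn += 1
    if tp + fp == 0 or tp + fn == 0 or tp == 0:
        if tp + fp + fn == 0:
            logger.debug("class %r absent from prediction and truth", cls)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 0.0 if precision + recall == 0 else (
            2 * precision * recall / (precision + recall)
        )
        return precision, recall, f1
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return precision, recall, 2 * precision * recall / (precision + recall)


def extract_segments(labels: LabelSequence | str) -> list[SegmentSpan]:
    """Maximal constant-label runs, 1-based; '.' breaks runs."""
    s = _labels(labels)
    spans: list[SegmentSpan] = []
    start = None
    current = None
    for i, c in enumerate(s, start=1):
        if c == UNLABELED:
            if current is not None:
                spans.append(SegmentSpan(current, start, i - 1))
                current = None
            continue
        if c != current:
            if current is not None:
                spans.append(SegmentSpan(current, start, i - 1))
            current, start = c, i
    if current is not None:
        spans.append(SegmentSpan(current, start, len(s)))
    return spans


#: Minimum overlap (residues) for a membrane segment to count as matched.
TM_SEGMENT_MIN_OVERLAP = 5


def _min_overlap(label: str) -> int:
    return TM_SEGMENT_MIN_OVERLAP if label == "M" else 1


def _match_segments(
    pred_spans: list[SegmentSpan], true_spans: list[SegmentSpan]
) -> int:
    """One-to-one greedy matching in sequence order, per label class.

    The two-pointer sweep (advance whichever segment ends first) is
    symmetric in its arguments, so swapping prediction and truth swaps
    sensitivity and precision exactly.
    """
    matched = 0
    labels = {s.label for s in pred_spans} | {s.label for s in true_spans}
    for lab in labels:
        ps = [s for s in pred_spans if s.label == lab]
        ts = [s for s in true_spans if s.label == lab]
        need = _min_overlap(lab)
        i = j = 0
        while i < len(ps) and j < len(ts):
            if ps[i].overlap(ts[j]) >= need:
                matched += 1
                i += 1
                j += 1
            elif ps[i].end < ts[j].end:
                i += 1
            else:
                j += 1
    return matched


def tm_segment_metrics(
    pred: LabelSequence | str, true: LabelSequence | str
) -> tuple[float, float]:
    """Segment-level (sensitivity, precision) for one SP+TM labeling.

    Membrane ('M') segments match with >= 5 residues of overlap; all other
    segment types need a single overlapping residue.  Matching is one-to-one
    greedy in sequence order.
    """
    p, t = _paired(pred, true)
    pred_spans = extract_segments(p)
    true_spans = extract_segments(t)
    matched = _match_segments(pred_spans, true_spans)
    sensitivity = matched / len(true_spans) if true_spans else 0.0
    precision = matched / len(pred_spans) if pred_spans else 0.0
    return sensitivity, precision


def tm_segment_report(
    pairs: Iterable[tuple[LabelSequence | str, LabelSequence | str]]
) -> dict[str, float]:
    """Pooled and per-protein-mean segment sensitivity/precision."""
    matched = n_true = n_pred = 0
    sens, prec = [], []
    for pred, true in pairs:
        p, t = _paired(pred, true)
        ps, ts = extract_segments(p), extract_segments(t)
        m = _match_segments(ps, ts)
        matched += m
        n_true += len(ts)
        n_pred += len(ps)
        sens.append(m / len(ts) if ts else 0.0)
        prec.append(m / len(ps) if ps else 0.0)
    return {
        "segment_sensitivity_pooled": matched / n_true if n_true else 0.0,
        "segment_precision_pooled": matched / n_pred if n_pred else 0.0,
        "segment_sensitivity_mean": float(np.mean(sens)) if sens else 0.0,
        "segment_precision_mean": float(np.mean(prec)) if prec else 0.0,
    }


def sp_protein_accuracy(
    preds: Sequence[LabelSequence | str], trues: Sequence[LabelSequence | str]
) -> float:
    """Protein-level accuracy of signal-peptide presence.

    A protein is deemed to have a predicted signal peptide iff any residue
    carries the label 'S'; same rule defines the truth.
    """
    if len(preds) != len(trues):
        raise DataError("prediction/truth protein counts differ")
    if not preds:
        raise DataError("no proteins given")
    correct = sum(
        ("S" in _labels(p)) == ("S" in _labels(t)) for p, t in zip(preds, trues)
    )
    return correct / len(preds)


_HEPTAD = set("abcdefg")


def cc_percent_correct(
    pred: LabelSequence | str, true: LabelSequence | str
) -> float:
    """Coiled-coil structure-region agreement rate.

    Positions match when both labels are heptad letters (any register letter
    matches any other, e.g. 'a' matches 'c') or both are 'N'; unlabeled true
    positions are excluded.
    """
    p, t = _paired(pred, true)
    match = labeled = 0
    for a, b in zip(p, t):
        if b == UNLABELED:
            continue
        labeled += 1
        if (a in _HEPTAD and b in _HEPTAD) or (a == b == "N"):
            match += 1
    if labeled == 0:
        raise DataError("cc_percent_correct undefined: no labeled positions")
    return match / labeled


def z_test(acc1: float, acc2: float, n: int) -> float:
    """Two-proportion pooled Z-test (two-sided), equal group sizes n.

    Degenerate pooled rates (0 or 1) give p = 1 with a log flag.
    """
    if n <= 0:
        raise DataError("z_test needs n > 0")
    if not (0 <= acc1 <= 1 and 0 <= acc2 <= 1):
        raise DataError("accuracies must lie in [0, 1]")
    pooled = (acc1 + acc2) / 2.0
    if pooled in (0.0, 1.0):
        logger.warning("z_test: degenerate pooled rate %.3f; p = 1", pooled)
        return 1.0
    se = np.sqrt(pooled * (1 - pooled) * 2.0 / n)
    z = (acc1 - acc2) / se
    return float(2.0 * norm.sf(abs(z)))


def knn_overlap(
    emb: EmbeddingTable, matrix: np.ndarray, k: int,
    symbols: str = AMINO_ACIDS,
) -> float:
    """k-NN agreement between an embedding and a substitution matrix.

    For each of the 20 residues, take the k nearest neighbors by Euclidean
    distance in the embedding and the k highest-scoring substitution
    partners (self excluded, ties broken by dictionary order); the overlap
    rate is |intersection| / (20 k).
    """
    if k >= len(symbols):
        raise ConfigError(f"k must be < {len(symbols)}, got {k}")
    if k < 1:
        raise ConfigError("k must be >= 1")
    matrix = np.asarray(matrix)
    cols = np.array([emb.symbols.index(s) for s in symbols])
    vectors = emb.weights[:, cols].T  # (20, d)
    inter = 0
    n = len(symbols)
    for i in range(n):
        dists = np.linalg.norm(vectors - vectors[i], axis=1)
        dists[i] = np.inf
        emb_nn = set(np.lexsort((np.arange(n), dists))[:k].tolist())
        scores = matrix[i].astype(float).copy()
        scores[i] = -np.inf
        mat_nn = set(np.lexsort((np.arange(n), -scores))[:k].tolist())
        inter += len(emb_nn & mat_nn)
    return inter / (n * k)


def evaluate_task(
    pairs: Sequence[tuple[LabelSequence | str, LabelSequence | str]],
    alphabet: Sequence[str],
    task_name: str = "",
) -> EvalReport:
    """Pooled EvalReport over proteins, with task-specific extras.

    Extras: 'sp' adds the protein-level signal-peptide accuracy, 'tm' adds
    the segment-level sensitivity/precision (pooled and per-protein means),
    'cc' adds the percent-correct structure-region rate.
    """
    if not pairs:
        raise DataError("no proteins to evaluate")
    pred_cat = "".join(_labels(p) for p, _ in pairs)
    true_cat = "".join(_labels(t) for _, t in pairs)
    per_class: dict[str, dict[str, float]] = {}
    for cls in alphabet:
        precision, recall, f1 = per_class_prf(pred_cat, true_cat, cls, alphabet)
        support = sum(c == cls for c in true_cat)
        tp = sum(a == b == cls for a, b in zip(pred_cat, true_cat))
        per_class[cls] = {
            "precision": precision, "recall": recall, "f1": f1,
            "support": float(support), "tp": float(tp),
        }
    report = EvalReport(q_score(pred_cat, true_cat), per_class)
    if task_name == "sp":
        report.extras["protein_accuracy"] = sp_protein_accuracy(
            [p for p, _ in pairs], [t for _, t in pairs]
        )
    elif task_name == "tm":
        report.extras.update(tm_segment_report(pairs))
    elif task_name == "cc":
        rates = [cc_percent_correct(p, t) for p, t in pairs]
        report.extras["percent_correct"] = float(np.mean(rates))
    return report
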