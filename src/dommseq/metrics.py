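"""External clustering evaluation: accuracy, F1-measure and NMI.

Predicted cluster ids and ground-truth class labels are arbitrary, so
accuracy and F1 first establish a one-to-one predicted→true
correspondence by optimal assignment on the contingency table (the
assignment maximizing the total matched count).  NMI needs no matching:
it is 2·I(C,G) / (H(C)+H(G)) with mutual information and entropies
computed from the contingency table in natural log (the base cancels).
All three metrics lie in [0,1] and are invariant under relabeling.
"""

from __future__ import annotations

from typing import Sequence as TypingSequence

import numpy as np
from scipy.optimize import linear_sum_assignment


def contingency_table(pred: TypingSequence, truth: TypingSequence) -> np.ndarray:
    """Counts |C_i ∩ G_j| for predicted clusters i (rows) and true classes j."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same length")
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    T = np.zeros((pi.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(T, (pi, ti), 1)
    return T


def match_labels(T: np.ndarray) -> dict[int, int]:
    """Optimal one-to-one predicted→true assignment maximizing matched count.

    Rectangular tables are allowed; surplus rows/columns stay unmatched.
    """
    rows, cols = linear_sum_assignment(-np.asarray(T))
    return dict(zip(rows.tolist(), cols.tolist()))


def accuracy(pred: TypingSequence, truth: TypingSequence) -> float:
    """Fraction of sequences whose matched cluster equals their true class."""
    T = contingency_table(pred, truth)
    mapping = match_labels(T)
    matched = sum(T[i, j] for i, j in mapping.items())
    return matched / T.sum()


def f1(pred: TypingSequence, truth: TypingSequence, average: str = "weighted") -> float:
    """Set-matching F1: per matched (cluster, class) pair, precision |C∩G|/|C|
    and recall |C∩G|/|G| give a per-class F1; scores are averaged weighted by
    true class size (``average="macro"`` for the unweighted mean).  The
    one-to-one matching maximizes the averaged F1 itself, which makes the
    score invariant under relabeling even when several matchings tie on
    matched counts.  True classes left unmatched contribute 0.
    """
    T = contingency_table(pred, truth)
    class_sizes = T.sum(axis=0)
    cluster_sizes = T.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = T / cluster_sizes[:, None]
        r = T / class_sizes[None, :]
        F = np.where((p + r) > 0, 2 * p * r / np.where((p + r) > 0, p + r, 1), 0.0)
    F = np.nan_to_num(F)
    if average == "macro":
        weights = np.ones_like(class_sizes, dtype=float)
    elif average == "weighted":
        weights = class_sizes.astype(float)
    else:
        raise ValueError(f"unknown average {average!r}")
    rows, cols = linear_sum_assignment(-(F * weights[None, :]))
    return float((F[rows, cols] * weights[cols]).sum() / weights.sum())


def nmi(pred: TypingSequence, truth: TypingSequence) -> float:
    """Normalized mutual information 2·I(C,G)/(H(C)+H(G)); 0/0 defined as 1."""
    T = contingency_table(pred, truth).astype(float)
    N = T.sum()
    pc = T.sum(axis=1) / N
    pg = T.sum(axis=0) / N
    mi = 0.0
    for i in range(T.shape[0]):
        for j in range(T.shape[1]):
            nij = T[i, j]
            if nij > 0:
                mi += (nij / N) * np.log(N * nij / (T[i].sum() * T[:, j].sum()))
    h_c = -np.sum(pc[pc > 0] * np.log(pc[pc > 0]))
    h_g = -np.sum(pg[pg > 0] * np.log(pg[pg > 0]))
    if h_c + h_g == 0:
        return 1.0  # both partitions single-class: identical
    return float(2.0 * mi / (h_c + h_g))


def evaluate(pred: TypingSequence, truth: TypingSequence) -> dict[str, float]:
    """All three metrics at once."""
    return {"accuracy": accuracy(pred, truth),
            "f1": f1(pred, truth),
            "nmi": nmi(pred, truth)}
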