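"""Dynamic-order Markov model: cluster models, dissimilarity, objective.

A cluster C is represented by the pattern set Θ mined by the SPD plus a
table of model conditionals P̂_M(s|θ).  Per sequence, the conditional
P̂_S(s|θ) = [n(θs,S)/n(θ,S)]·[n(θ,S)/|S|] weights the experience
probability by the pattern's frequency in S; algebraically it reduces to
n(θs,S)/|S| (0 when the pattern is absent).  The model conditional is
the length-weighted quadratic mean of the per-sequence values,

    P̂_M(s|θ) = sqrt( Σ_{S∈C} |S|·P̂_S(s|θ)² / Σ_{S∈C} |S| ),

the minimizer of the chi-square-style clustering objective.  The
sequence–cluster dissimilarity accumulates a chi-square-style
discrepancy over all (pattern, next-symbol) cells:

    d(S,C) = (1/|Θ|) Σ_{s∈Σ} Σ_{θ∈Θ} (P̂_S(s|θ) − P̂_M(s|θ))² / max(P̂_M(s|θ), ε),

with floor ε = 1e-6 guarding zero model conditionals; cells where both
probabilities are zero contribute nothing.  The leading 1/|Θ| makes
dissimilarities comparable across models with different pattern-set
sizes: the underlying generative form charges each sequence position
once, and without the normalization a model that happens to mine more
patterns accumulates more discrepancy terms for *every* sequence, which
destabilizes relocation (clusters with rich pattern sets bleed members
regardless of fit).  Set ``normalize=False`` for the raw sum.  The
clustering objective SCError is the sum of d(S, C_k) over all clusters
and members.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .seqio import Alphabet, Sequence, SequenceSet
from .spd import Pattern, encode, pattern_next_count, pattern_next_counts

logger = logging.getLogger("dommseq")

EPSILON = 1e-6  # floor for zero model conditionals in the dissimilarity


@dataclass
class ClusterModel:
    """Pattern set Θ with estimated conditionals P̂_M(s|θ) for one cluster."""

    patterns: list[Pattern]
    conditionals: np.ndarray      # (|Θ|, |Σ|)
    alphabet: Alphabet
    member_lengths: list[int]
    tau: float

    @property
    def total_length(self) -> int:
        return sum(self.member_lengths)

    def to_json(self) -> str:
        return json.dumps(
            {
                "tau": self.tau,
                "alphabet": list(self.alphabet.symbols),
                "patterns": [
                    {"pattern": str(p), "count": p.count, "is_sparse": p.is_sparse}
                    for p in self.patterns
                ],
                "conditionals": self.conditionals.tolist(),
                "member_lengths": self.member_lengths,
            },
            indent=1,
        )


def p_hat_seq(s: str, theta: Pattern, S: Sequence, A: Alphabet) -> float:
    """P̂_S(s|θ) = [n(θs,S)/n(θ,S)]·[n(θ,S)/|S|] = n(θs,S)/|S| (0 if θ absent)."""
    return pattern_next_count(theta, s, S, A) / len(S)


def seq_conditionals(S: Sequence, patterns: list[Pattern], A: Alphabet) -> np.ndarray:
    """Matrix (|Θ|, |Σ|) of P̂_S(s|θ) for one sequence."""
    codes = encode(S, A)
    n = len(S)
    out = np.empty((len(patterns), A.size))
    for i, theta in enumerate(patterns):
        out[i] = pattern_next_counts(theta, codes, A) / n
    return out


def fit_model(C: SequenceSet, Theta: list[Pattern], tau: float = 0.0) -> ClusterModel:
    """Estimate P̂_M(s|θ) over Θ×Σ as the length-weighted quadratic mean."""
    A = C.alphabet
    assert A is not None
    lengths = [len(S) for S in C]
    if not Theta:
        logger.warning("fitting cluster model with empty pattern set")
        cond = np.zeros((0, A.size))
        return ClusterModel(patterns=[], conditionals=cond, alphabet=A,
                            member_lengths=lengths, tau=tau)
    total = float(sum(lengths))
    acc = np.zeros((len(Theta), A.size))
    for S, n in zip(C, lengths):
        acc += n * seq_conditionals(S, Theta, A) ** 2
    cond = np.sqrt(acc / total)
    return ClusterModel(patterns=list(Theta), conditionals=cond, alphabet=A,
                        member_lengths=lengths, tau=tau)


def dissim(S: Sequence, M: ClusterModel, epsilon: float = EPSILON,
           normalize: bool = True) -> float:
    """Chi-square-style dissimilarity d(S,C) between a sequence and a cluster.

    With ``normalize=True`` (default) the cell discrepancies are averaged
    over the |Θ| patterns; ``normalize=False`` gives the raw sum.
    """
    if not M.patterns:
        return 0.0
    P_S = seq_conditionals(S, M.patterns, M.alphabet)
    return dissim_from_conditionals(P_S, M.conditionals, epsilon, normalize)


def dissim_from_conditionals(
    P_S: np.ndarray, P_M: np.ndarray, epsilon: float = EPSILON,
    normalize: bool = True,
) -> float:
    """d from precomputed per-sequence and model conditional tables."""
    both_zero = (P_S == 0) & (P_M == 0)
    denom = np.maximum(P_M, epsilon)
    terms = (P_S - P_M) ** 2 / denom
    terms[both_zero] = 0.0
    total = float(terms.sum())
    return total / P_S.shape[0] if normalize else total


def similarity(S: Sequence, M: ClusterModel, epsilon: float = EPSILON) -> float:
    """Generative-probability form exp(−d(S,C)); convenience accessor."""
    return float(np.exp(-dissim(S, M, epsilon)))


def sc_error(partition: list[tuple[SequenceSet, ClusterModel]],
             epsilon: float = EPSILON) -> float:
    """Sum of Clustering Error: Σ_k Σ_{S∈C_k} d(S, C_k)."""
    total = 0.0
    for C, M in partition:
        for S in C:
            total += dissim(S, M, epsilon)
    return total
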