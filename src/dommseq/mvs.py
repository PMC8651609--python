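"""Sequence vectorization: the Markov Vector of Sequence (MVS).

Each sequence is summarized by its first-order Markov statistics:

* ``V_F`` — symbol frequency vector (length |Σ|, sums to 1),
* ``M_O`` — transition occurrence matrix (|Σ|×|Σ| adjacent-pair counts),
* ``M_P`` — Bayesian-smoothed transition probabilities,
  p_ij = (η_ij/η_i)·(η_i/(η_i+O_i)) + O_ij/(η_i+O_i)
  with η_ij = 1/|Σ|, η_i = Σ_j η_ij = 1 and O_i the row sum,
* ``M_FP = diag(V_F)·M_P`` — frequency-weighted probabilities,
* ``mvs`` — the row-major flattening of M_FP, length |Σ|².

The smoothing is a Dirichlet-style shrinkage toward the uniform
distribution: an all-zero row maps to 1/|Σ| everywhere, and as the row
total grows the entries converge to the empirical O_ij/O_i.  Because M_P
rows sum to 1 and V_F sums to 1, the MVS entries always sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import Alphabet, Sequence, SequenceSet


@dataclass(frozen=True)
class MarkovVector:
    """Vectorization bundle for one sequence."""

    V_F: np.ndarray    # (|Σ|,)
    M_O: np.ndarray    # (|Σ|, |Σ|) integer counts
    M_P: np.ndarray    # (|Σ|, |Σ|) row-stochastic
    M_FP: np.ndarray   # (|Σ|, |Σ|)
    mvs: np.ndarray    # (|Σ|²,)


def symbol_frequencies(S: Sequence, A: Alphabet) -> np.ndarray:
    """Relative frequency of every alphabet symbol in ``S``; sums to 1."""
    freq = np.zeros(A.size)
    for sym in S:
        freq[A.index(sym)] += 1
    return freq / len(S)


def transition_occurrences(S: Sequence, A: Alphabet) -> np.ndarray:
    """Adjacent-pair counts over a sliding window of width 2; total |S|−1."""
    M = np.zeros((A.size, A.size), dtype=np.int64)
    for a, b in zip(S.symbols, S.symbols[1:]):
        M[A.index(a), A.index(b)] += 1
    return M


def bayes_transition(M_O: np.ndarray) -> np.ndarray:
    """Bayesian-smoothed transition probabilities from a count matrix.

    Row i: p_ij = (η_ij/η_i)·(η_i/(η_i+O_i)) + O_ij/(η_i+O_i), where the
    prior pseudo-counts are η_ij = 1/|Σ| (so η_i = 1) and O_i is the row
    sum.  Every row sums to 1 and every entry is strictly positive.
    """
    M_O = np.asarray(M_O, dtype=float)
    k = M_O.shape[0]
    eta_ij = 1.0 / k
    eta_i = 1.0
    O_i = M_O.sum(axis=1, keepdims=True)
    return (eta_ij / eta_i) * (eta_i / (eta_i + O_i)) + M_O / (eta_i + O_i)


def weighted_transition(V_F: np.ndarray, M_P: np.ndarray) -> np.ndarray:
    """M_FP = diag(V_F)·M_P — row i of M_P scaled by the frequency of symbol i."""
    V_F = np.asarray(V_F, dtype=float)
    return V_F[:, None] * np.asarray(M_P, dtype=float)


def markov_vector(S: Sequence, A: Alphabet) -> MarkovVector:
    """Full vectorization chain for one sequence."""
    V_F = symbol_frequencies(S, A)
    M_O = transition_occurrences(S, A)
    M_P = bayes_transition(M_O)
    M_FP = weighted_transition(V_F, M_P)
    return MarkovVector(V_F=V_F, M_O=M_O, M_P=M_P, M_FP=M_FP, mvs=M_FP.ravel())


def mvs(S: Sequence, A: Alphabet) -> np.ndarray:
    """Row-major flattening of M_FP; length |Σ|², entries sum to 1."""
    return markov_vector(S, A).mvs


def vectorize_set(data: SequenceSet) -> np.ndarray:
    """N×|Σ|² MVS matrix; row order follows the input order."""
    A = data.alphabet
    assert A is not None
    return np.vstack([mvs(S, A) for S in data])


def pair_names(A: Alphabet, sep: str = ">") -> list[str]:
    """Column names of the MVS matrix in row-major order, e.g. 'a>b'."""
    return [f"{a}{sep}{b}" for a in A.symbols for b in A.symbols]


def mvs_frame(data: SequenceSet):
    """MVS matrix as a pandas DataFrame (rows = sequence ids, columns = pairs)."""
    import pandas as pd

    A = data.alphabet
    assert A is not None
    return pd.DataFrame(vectorize_set(data),
                        index=[S.id for S in data], columns=pair_names(A))
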