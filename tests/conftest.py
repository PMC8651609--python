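"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from dommseq import Alphabet, Sequence, SequenceSet
from dommseq.spd import Pattern, Wildcard


# ---------------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive and independent of the package)
# ---------------------------------------------------------------------------

def substring_count(corpus: list[str], sub: tuple[str, ...] | str) -> int:
    """Overlapping sliding-window occurrences of ``sub`` across the corpus."""
    sub = tuple(sub)
    m = len(sub)
    total = 0
    for s in corpus:
        toks = tuple(s)
        for i in range(len(toks) - m + 1):
            if toks[i:i + m] == sub:
                total += 1
    return total


def brute_pattern_count(corpus: list[str], elements) -> int:
    """Sum of substring counts over every concrete instantiation of a pattern.

    ``elements`` mixes single symbols and iterables of symbols (wildcards).
    """
    choices = [[e] if isinstance(e, str) else sorted(e) for e in elements]
    return sum(substring_count(corpus, inst) for inst in product(*choices))


def pattern_as_choices(p: Pattern):
    return [e if isinstance(e, str) else e.subset for e in p.elements]


def random_corpus(rng: np.random.Generator, max_symbols: int = 4,
                  max_seqs: int = 10, max_len: int = 30) -> list[str]:
    k = int(rng.integers(2, max_symbols + 1))
    alphabet = "abcd"[:k]
    n = int(rng.integers(1, max_seqs + 1))
    out = []
    for _ in range(n):
        length = int(rng.integers(1, max_len + 1))
        out.append("".join(rng.choice(list(alphabet), size=length)))
    return out


def corpus_to_set(corpus: list[str]) -> SequenceSet:
    return SequenceSet([Sequence(f"s{i}", tuple(s)) for i, s in enumerate(corpus)])


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def fig_corpus() -> SequenceSet:
    """91 length-4 sequences: GTGT x25, GSGT x16, GVGT x18, GTIT x17, GTAT x15."""
    seqs = []
    for word, mult in [("GTGT", 25), ("GSGT", 16), ("GVGT", 18),
                       ("GTIT", 17), ("GTAT", 15)]:
        for i in range(mult):
            seqs.append(Sequence(f"{word}_{i}", tuple(word)))
    return SequenceSet(seqs)


@pytest.fixture(scope="session")
def worked_example():
    """Printed (V_F, M_O) pair of the three-symbol worked example."""
    return (np.array([0.500, 0.286, 0.214]),
            np.array([[3, 5, 5], [7, 0, 1], [3, 3, 0]]))


@pytest.fixture
def abc_alphabet() -> Alphabet:
    return Alphabet(("a", "b", "c"))
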