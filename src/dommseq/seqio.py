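"""Sequence data model, readers/writers and the synthetic dataset generator.

Sequences are ordered lists of categorical symbols over a finite alphabet
Σ.  Symbols may be single characters (protein/RNA alphabets, FASTA input)
or multi-character tokens (discretized sensor states, whitespace-delimited
input), so a sequence is stored as a tuple of strings rather than a string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("dommseq")


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alphabet:
    """Ordered finite symbol set Σ.

    Symbol order is fixed at construction and stable for the lifetime of
    the object; every matrix/vector produced downstream indexes rows and
    columns in this order.
    """

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet contains duplicate symbols")
        if len(self.symbols) < 2:
            logger.warning("alphabet has fewer than 2 symbols (size=%d)", len(self.symbols))

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    @property
    def _index(self) -> dict[str, int]:
        # cached lazily on the instance despite frozen dataclass
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {s: i for i, s in enumerate(self.symbols)}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"symbol {symbol!r} not in alphabet {self.symbols}") from None


@dataclass(frozen=True)
class Sequence:
    """One categorical sequence S = s1 s2 ... sn with an identifier."""

    id: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __getitem__(self, i):
        return self.symbols[i]


@dataclass
class SequenceSet:
    """A dataset (or cluster) of sequences, optionally with ground-truth labels."""

    sequences: list[Sequence]
    labels: list[str] | None = None
    alphabet: Alphabet | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.sequences) < 1:
            raise ValueError("sequence set is empty")
        if self.labels is not None and len(self.labels) != len(self.sequences):
            raise ValueError("labels do not align 1:1 with sequences")
        if self.alphabet is None:
            self.alphabet = infer_alphabet(self)

    @property
    def N(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def subset(self, indices: TypingSequence[int]) -> "SequenceSet":
        """A new set with the same alphabet, restricted to ``indices``."""
        return SequenceSet(
            [self.sequences[i] for i in indices],
            labels=[self.labels[i] for i in indices] if self.labels is not None else None,
            alphabet=self.alphabet,
        )


def infer_alphabet(data: SequenceSet | Iterable[Sequence]) -> Alphabet:
    """Sorted union of all symbols observed in ``data``."""
    seqs = data.sequences if isinstance(data, SequenceSet) else list(data)
    symbols: set[str] = set()
    for s in seqs:
        symbols.update(s.symbols)
    if len(symbols) < 2:
        logger.warning("inferred alphabet has size %d (< 2)", len(symbols))
        if not symbols:
            raise ValueError("cannot infer alphabet: no symbols observed")
    return Alphabet(tuple(sorted(symbols)))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, uppercase: bool = False) -> SequenceSet:
    """Read a FASTA file into a character-tokenized :class:`SequenceSet`.

    Multi-line records are supported.  ``uppercase=True`` folds residues to
    upper case; the default preserves case verbatim.
    """
    path = Path(path)
    records = list(_BioSeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found (empty or non-FASTA file)")
    sequences = []
    for rec in records:
        text = str(rec.seq)
        if uppercase:
            text = text.upper()
        if not text:
            raise ValueError(f"{path}: record {rec.id!r} has zero-length sequence")
        sequences.append(Sequence(rec.id, tuple(text)))
    return SequenceSet(sequences)


def write_fasta(data: SequenceSet, path: str | Path) -> None:
    """Write a character-tokenized set back to FASTA (symbols concatenated)."""
    records = [
        _BioSeqRecord(_BioSeq("".join(s.symbols)), id=s.id, description="")
        for s in data
    ]
    _BioSeqIO.write(records, str(path), "fasta")


def read_lines(path: str | Path, delimiter: str | None = None) -> SequenceSet:
    """Read a plain-text file, one sequence per line.

    ``delimiter=None`` tokenizes each line per character; ``"whitespace"``
    splits on whitespace into multi-character symbols (needed for alphabets
    whose symbols are multi-character tokens).  Blank interior lines are
    skipped with a warning.
    """
    path = Path(path)
    sequences = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                logger.warning("%s:%d: blank line skipped", path, lineno)
                continue
            if delimiter == "whitespace":
                toks = tuple(line.split())
            elif delimiter is None:
                toks = tuple(line)
            else:
                raise ValueError(f"unsupported delimiter {delimiter!r}")
            sequences.append(Sequence(f"seq{lineno}", toks))
    if not sequences:
        raise ValueError(f"{path}: no sequences found")
    return SequenceSet(sequences)


def write_lines(data: SequenceSet, path: str | Path, delimiter: str | None = None) -> None:
    sep = " " if delimiter == "whitespace" else ""
    with open(path, "w") as fh:
        for s in data:
            fh.write(sep.join(s.symbols) + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``id<TAB>class`` into a mapping."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>class', got {line!r}")
            labels[parts[0]] = parts[1]
    return labels


def write_labels(data: SequenceSet, path: str | Path) -> None:
    if data.labels is None:
        raise ValueError("sequence set carries no labels")
    with open(path, "w") as fh:
        for s, lab in zip(data.sequences, data.labels):
            fh.write(f"{s.id}\t{lab}\n")


def attach_labels(data: SequenceSet, labels: Mapping[str, str]) -> SequenceSet:
    """Attach labels to ``data`` by sequence id; every id must be present."""
    missing = [s.id for s in data if s.id not in labels]
    if missing:
        raise ValueError(f"no label for sequence id(s): {missing[:5]}")
    return SequenceSet(
        list(data.sequences), labels=[labels[s.id] for s in data], alphabet=data.alphabet
    )


# ---------------------------------------------------------------------------
# Synthetic labeled-dataset generator
# ---------------------------------------------------------------------------

@dataclass
class MotifSpec:
    """A class-specific motif with optional noisy (wildcard-like) positions.

    ``elements`` is an ordered list where each item is either a single
    symbol (a fixed position) or a tuple of symbols (a noisy position: at
    each insertion, one member is drawn uniformly).  This emulates real
    motifs whose interior positions vary within a small residue subset, so
    that each concrete variant can be sub-frequent while the masked form
    is frequent.
    """

    elements: list[str | tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.elements)

    def realize(self, rng: np.random.Generator) -> list[str]:
        out = []
        for el in self.elements:
            if isinstance(el, tuple):
                out.append(el[rng.integers(len(el))])
            else:
                out.append(el)
        return out


@dataclass
class ClassSpec:
    """Generating process for one class: a first-order Markov chain plus motifs."""

    size: int
    transition: np.ndarray          # row-stochastic |Σ|×|Σ|
    motifs: list[MotifSpec] = field(default_factory=list)
    motif_rate: float = 0.0         # expected insertions per sequence (Poisson)
    motif_copies: int = 0           # if > 0: exactly this many copies of EACH motif
    initial: np.ndarray | None = None  # start distribution; default uniform


@dataclass
class SyntheticConfig:
    alphabet: Alphabet
    classes: dict[str, ClassSpec]
    length_mean: int = 200
    length_sd: int = 0              # 0 → fixed length
    min_length: int = 10


def _check_stochastic(P: np.ndarray, k: int, name: str) -> None:
    P = np.asarray(P, dtype=float)
    if P.shape != (k, k):
        raise ValueError(f"{name}: transition matrix must be {k}x{k}, got {P.shape}")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError(f"{name}: transition matrix is not row-stochastic")


def two_class_benchmark(
    n_per_class: int = 50,
    length: int = 200,
    cycle_weight: float = 0.08,
    motif_copies: int = 2,
) -> SyntheticConfig:
    """Canonical two-class benchmark configuration over Σ = {a,b,c,d}.

    Each class draws from a first-order chain mildly biased (weight
    ``cycle_weight`` against a uniform background) toward one of the two
    directed 4-cycles, so first-order statistics separate the classes
    only partially.  On top of the chain backbone, every sequence
    carries exactly ``motif_copies`` copies of each of three length-7
    motifs built like conserved protein domains:

        head · noisy · core (4 symbols) · tail

    The 4-symbol core and the tail are *shared* between the classes;
    the head symbol and the noisy position's 3-symbol subset are
    class-specific.  At the per-cluster support threshold (the cluster
    size), every concrete variant of a motif is sub-frequent while the
    wildcard-masked form is frequent — so the class-discriminative part
    of the motif is only reachable through sparse pattern mining, and a
    consecutive-only detector sees just the shared core.
    """
    A = Alphabet(("a", "b", "c", "d"))
    k = 4
    uniform = np.full((k, k), 1.0 / k)
    fwd = np.zeros((k, k))
    bwd = np.zeros((k, k))
    for i in range(k):
        fwd[i, (i + 1) % k] = 1.0   # a→b→c→d→a
        bwd[i, (i - 1) % k] = 1.0   # a→d→c→b→a
    P1 = (1 - cycle_weight) * uniform + cycle_weight * fwd
    P2 = (1 - cycle_weight) * uniform + cycle_weight * bwd
    cores = [("c", "a", "c", "b"), ("d", "b", "d", "a"), ("a", "c", "d", "b")]
    tails = ["d", "c", "a"]
    heads1, heads2 = ["a", "c", "b"], ["b", "d", "c"]
    subs1 = [("a", "b", "d"), ("b", "c", "d"), ("a", "c", "d")]
    subs2 = [("a", "c", "d"), ("a", "b", "c"), ("a", "b", "d")]
    motifs1 = [MotifSpec([heads1[j], subs1[j], *cores[j], tails[j]]) for j in range(3)]
    motifs2 = [MotifSpec([heads2[j], subs2[j], *cores[j], tails[j]]) for j in range(3)]
    return SyntheticConfig(
        alphabet=A,
        classes={
            "class1": ClassSpec(size=n_per_class, transition=P1,
                                motifs=motifs1, motif_copies=motif_copies),
            "class2": ClassSpec(size=n_per_class, transition=P2,
                                motifs=motifs2, motif_copies=motif_copies),
        },
        length_mean=length,
    )


def generate_synthetic(config: SyntheticConfig, seed: int) -> SequenceSet:
    """Draw a labeled dataset of Markov-chain sequences with embedded motifs.

    Each sequence is sampled from its class's first-order chain; a
    Poisson(``motif_rate``) number of motif instances (at least one when
    ``motif_rate`` > 0) is then written over the chain backbone at
    non-overlapping uniform positions, with noisy motif positions drawn
    uniformly from their symbol subsets.  Deterministic given ``seed``.
    """
    A = config.alphabet
    k = A.size
    rng = np.random.default_rng(seed)
    sequences: list[Sequence] = []
    labels: list[str] = []

    for cls_name, spec in config.classes.items():
        _check_stochastic(spec.transition, k, cls_name)
        for m in spec.motifs:
            for el in m.elements:
                syms = el if isinstance(el, tuple) else (el,)
                for s in syms:
                    if s not in A:
                        raise ValueError(f"{cls_name}: motif symbol {s!r} not in alphabet")
            if len(m) > config.min_length:
                raise ValueError(f"{cls_name}: motif longer than minimum sequence length")
        init = spec.initial if spec.initial is not None else np.full(k, 1.0 / k)
        P = np.asarray(spec.transition, dtype=float)
        for i in range(spec.size):
            if config.length_sd > 0:
                n = int(round(rng.normal(config.length_mean, config.length_sd)))
                n = max(n, config.min_length)
            else:
                n = config.length_mean
            states = np.empty(n, dtype=np.int64)
            states[0] = rng.choice(k, p=init)
            for t in range(1, n):
                states[t] = rng.choice(k, p=P[states[t - 1]])
            symbols = [A.symbols[s] for s in states]
            if spec.motifs and (spec.motif_rate > 0 or spec.motif_copies > 0):
                if spec.motif_copies > 0:
                    # deterministic copy number per motif (domain-like structure)
                    chosen = [m for m in spec.motifs for _ in range(spec.motif_copies)]
                else:
                    n_ins = max(1, rng.poisson(spec.motif_rate))
                    chosen = [spec.motifs[rng.integers(len(spec.motifs))]
                              for _ in range(n_ins)]
                occupied: list[tuple[int, int]] = []
                for motif in chosen:
                    m = len(motif)
                    for _attempt in range(50):
                        pos = int(rng.integers(0, n - m + 1))
                        if all(pos + m <= a or pos >= b for a, b in occupied):
                            symbols[pos:pos + m] = motif.realize(rng)
                            occupied.append((pos, pos + m))
                            break
            sequences.append(Sequence(f"{cls_name}_{i}", tuple(symbols)))
            labels.append(cls_name)

    return SequenceSet(sequences, labels=labels, alphabet=A)
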