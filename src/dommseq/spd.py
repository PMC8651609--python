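"""Sparse pattern detector (SPD): a probability suffix tree with wildcards.

A classic PST stores contexts most-recent-symbol first: the node reached
from the root by edges ``x, σ`` holds the context "σx", so a root-to-node
path spells the context right-to-left.  Each node carries the total
occurrence count of its context across the cluster (overlapping sliding
windows, summed over sequences, no cross-sequence windows).

The SPD transform walks the unpruned tree top-down.  At every kept node
the children are split by the support threshold τ into the frequent group
U (kept and recursed) and the sub-frequent group V.  If V is non-empty,
all V subtrees are merged element-wise into a single *wildcard* child:
its edge matches exactly the merged symbol subset and its counts are the
sums of the merged children's counts.  The merged subtree is kept (and
recursed with the same rule, which can nest further wildcards) iff its
root count reaches τ; otherwise it is discarded.  Sub-frequent children
are removed either way, so every retained node has count ≥ τ.  When no
merge ever triggers, the SPD is exactly a threshold-pruned PST — the
model decays to a plain variable-order Markov model.

Patterns are the maximal root-to-leaf paths, reversed into left-to-right
order.  Patterns that begin or end with a wildcard are not emitted: a
sparse pattern by definition masks only interior positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterator, Union

import numpy as np

from .seqio import Alphabet, Sequence, SequenceSet

logger = logging.getLogger("dommseq")


# ---------------------------------------------------------------------------
# Pattern elements and patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Wildcard:
    """A wildcard position matching exactly the symbols in ``subset``."""

    subset: frozenset[str]

    def __post_init__(self) -> None:
        if not self.subset:
            raise ValueError("wildcard subset is empty")

    def __str__(self) -> str:
        return "[" + "".join(sorted(self.subset)) + "]"


PatternElement = Union[str, Wildcard]


@dataclass(frozen=True)
class Pattern:
    """An ordered pattern of concrete symbols and wildcards, with its count.

    The first and last elements are always concrete; ``count`` is the
    pattern's total occurrence in the cluster the SPD was built on.
    """

    elements: tuple[PatternElement, ...]
    count: int = 0

    def __post_init__(self) -> None:
        if len(self.elements) < 1:
            raise ValueError("empty pattern")
        if isinstance(self.elements[0], Wildcard) or isinstance(self.elements[-1], Wildcard):
            raise ValueError("pattern must start and end with a concrete symbol")

    @property
    def is_sparse(self) -> bool:
        return any(isinstance(e, Wildcard) for e in self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __str__(self) -> str:
        return "".join(str(e) for e in self.elements)

    def codes(self, A: Alphabet) -> list[np.ndarray]:
        """Per position, the sorted array of matching symbol indices."""
        out = []
        for e in self.elements:
            if isinstance(e, Wildcard):
                out.append(np.array(sorted(A.index(s) for s in e.subset), dtype=np.int64))
            else:
                out.append(np.array([A.index(e)], dtype=np.int64))
        return out


# ---------------------------------------------------------------------------
# Tree nodes
# ---------------------------------------------------------------------------

@dataclass
class SPDNode:
    """Tree node; ``element`` is the edge label from the parent (None at root)."""

    element: PatternElement | None
    count: int = 0
    children: dict[str, "SPDNode"] = field(default_factory=dict)
    wildcard_child: "SPDNode | None" = None
    depth: int = 0

    def all_children(self) -> Iterator["SPDNode"]:
        yield from self.children.values()
        if self.wildcard_child is not None:
            yield self.wildcard_child

    def is_leaf(self) -> bool:
        return not self.children and self.wildcard_child is None


@dataclass
class SPDTree:
    root: SPDNode
    L: int
    tau: float
    alphabet: Alphabet

    def iter_nodes(self) -> Iterator[SPDNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.all_children())

    def node_for(self, context: tuple[str, ...]) -> SPDNode | None:
        """Node holding ``context`` (left-to-right), following concrete edges."""
        node = self.root
        for sym in reversed(context):
            node = node.children.get(sym)  # type: ignore[assignment]
            if node is None:
                return None
        return node

    def to_json(self) -> str:
        def enc(node: SPDNode) -> dict:
            return {
                "element": str(node.element) if node.element is not None else None,
                "count": node.count,
                "children": [enc(c) for c in node.all_children()],
            }
        return json.dumps(enc(self.root), indent=1)


# ---------------------------------------------------------------------------
# PST construction
# ---------------------------------------------------------------------------

def build_pst(C: SequenceSet, L: int) -> SPDTree:
    """Unpruned PST of all contexts of length ≤ L occurring in ``C``.

    The node for context x has a child for every context σx; counts are
    overlapping sliding-window occurrence totals over all sequences.  The
    root count is the total number of positions (Σ|S|).
    """
    if L < 1:
        raise ValueError("max depth L must be >= 1")
    A = C.alphabet
    assert A is not None
    root = SPDNode(element=None)
    for S in C:
        syms = S.symbols
        n = len(syms)
        root.count += n
        for j in range(n):  # j = end position of the context
            node = root
            for d in range(min(L, j + 1)):
                sym = syms[j - d]
                child = node.children.get(sym)
                if child is None:
                    child = SPDNode(element=sym, depth=node.depth + 1)
                    node.children[sym] = child
                child.count += 1
                node = child
    return SPDTree(root=root, L=L, tau=0.0, alphabet=A)


# ---------------------------------------------------------------------------
# SPD transform: merge sub-frequent siblings, prune
# ---------------------------------------------------------------------------

def _merge_subtrees(nodes: list[SPDNode], depth: int) -> SPDNode:
    """Element-wise merge of sibling subtrees into one wildcard-rooted subtree."""
    subset: set[str] = set()
    for nd in nodes:
        el = nd.element
        if isinstance(el, Wildcard):  # cannot happen: V children are concrete
            subset.update(el.subset)
        else:
            subset.add(el)  # type: ignore[arg-type]
    merged = SPDNode(
        element=Wildcard(frozenset(subset)),
        count=sum(nd.count for nd in nodes),
        depth=depth,
    )
    by_symbol: dict[str, list[SPDNode]] = {}
    for nd in nodes:
        for sym, child in nd.children.items():
            by_symbol.setdefault(sym, []).append(child)
    for sym, group in by_symbol.items():
        sub = _merge_subtrees(group, depth + 1)
        # concrete edge inside a merged subtree keeps its own symbol
        sub.element = sym
        merged.children[sym] = sub
    return merged


def _spd_transform(node: SPDNode, tau: float) -> None:
    """Apply the U/V split, wildcard merge and pruning below ``node`` in place."""
    U = {s: c for s, c in node.children.items() if c.count >= tau}
    V = [c for s, c in node.children.items() if c.count < tau]
    node.children = U
    for child in U.values():
        _spd_transform(child, tau)
    if V:
        merged = _merge_subtrees(V, depth=node.depth + 1)
        if merged.count >= tau:
            node.wildcard_child = merged
            _spd_transform(merged, tau)
        # else: discarded together with its sub-frequent sources


def build_spd(
    C: SequenceSet,
    L: int,
    tau: float | str = "auto",
    sparse: bool = True,
) -> SPDTree:
    """Build the sparse pattern detector on cluster ``C``.

    ``tau="auto"`` sets the support threshold to the number of sequences
    in the cluster (a frequent pattern should occur at least once per
    sequence on average).  ``sparse=False`` disables wildcard merging and
    yields a plain threshold-pruned PST (the consecutive-only ablation).
    """
    if tau == "auto":
        tau_val = float(C.N)
    else:
        tau_val = float(tau)  # type: ignore[arg-type]
        if tau_val <= 0:
            raise ValueError("support threshold tau must be positive")
    tree = build_pst(C, L)
    if sparse:
        _spd_transform(tree.root, tau_val)
    else:
        _prune_only(tree.root, tau_val)
    tree.tau = tau_val
    return tree


def _prune_only(node: SPDNode, tau: float) -> None:
    node.children = {s: c for s, c in node.children.items() if c.count >= tau}
    for child in node.children.values():
        _prune_only(child, tau)


# ---------------------------------------------------------------------------
# Pattern extraction
# ---------------------------------------------------------------------------

def extract_patterns(T: SPDTree) -> list[Pattern]:
    """All longest frequent patterns of the SPD.

    A valid pattern starts and ends with a concrete symbol (a sparse
    pattern masks only interior positions), so the edge path to its node,
    reversed into left-to-right order, must be concrete at both ends.  A
    valid pattern is emitted iff it is maximal: no descendant of its node
    spells a valid pattern.  In particular a node whose only surviving
    descendants are wildcard-edge chains still emits its own pattern.
    """
    patterns: list[Pattern] = []

    def walk(node: SPDNode, path: list[PatternElement]) -> bool:
        emitted_below = False
        for child in node.all_children():
            emitted_below |= walk(child, path + [child.element])  # type: ignore[list-item]
        if emitted_below:
            return True
        if not path:
            return False
        elements = tuple(reversed(path))
        if isinstance(elements[0], Wildcard) or isinstance(elements[-1], Wildcard):
            return False
        patterns.append(Pattern(elements=elements, count=node.count))
        return True

    walk(T.root, [])
    if not patterns:
        logger.warning("SPD yielded no patterns (tau=%s too high?)", T.tau)
    # deterministic order: by length then rendered form
    patterns.sort(key=lambda p: (len(p), str(p)))
    return patterns


# ---------------------------------------------------------------------------
# Pattern occurrence counting
# ---------------------------------------------------------------------------

def encode(S: Sequence, A: Alphabet) -> np.ndarray:
    """Integer codes of a sequence under the alphabet's symbol order."""
    idx = A._index
    return np.fromiter((idx[s] for s in S.symbols), dtype=np.int64, count=len(S))


def _match_positions(codes: np.ndarray, elem_codes: list[np.ndarray], k: int) -> np.ndarray:
    """Boolean mask over start positions where the pattern matches."""
    m = len(elem_codes)
    n = len(codes)
    if m > n:
        return np.zeros(0, dtype=bool)
    ok = np.ones(n - m + 1, dtype=bool)
    for offset, codes_at in enumerate(elem_codes):
        window = codes[offset: offset + n - m + 1]
        if len(codes_at) == 1:
            ok &= window == codes_at[0]
        else:
            table = np.zeros(k, dtype=bool)
            table[codes_at] = True
            ok &= table[window]
    return ok


def pattern_count(theta: Pattern, S: Sequence, A: Alphabet) -> int:
    """n(θ,S): overlapping occurrences of θ in S, wildcards matching their subsets."""
    return int(_match_positions(encode(S, A), theta.codes(A), A.size).sum())


def pattern_next_count(theta: Pattern, s: str, S: Sequence, A: Alphabet) -> int:
    """n(θs,S): occurrences of θ immediately followed by symbol ``s``."""
    return int(pattern_next_counts(theta, encode(S, A), A)[A.index(s)])


def pattern_next_counts(theta: Pattern, codes: np.ndarray, A: Alphabet) -> np.ndarray:
    """Vector over Σ of n(θσ,S), computed in one scan from precomputed codes."""
    k = A.size
    ok = _match_positions(codes, theta.codes(A), k)
    m = len(theta)
    counts = np.zeros(k, dtype=np.int64)
    if len(ok) == 0:
        return counts
    starts = np.flatnonzero(ok)
    starts = starts[starts + m < len(codes)]  # occurrence at sequence end has no successor
    if len(starts):
        counts = np.bincount(codes[starts + m], minlength=k).astype(np.int64)
    return counts
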