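"""Sparse pattern detector tests: PST counts, merging, pruning, extraction."""

import numpy as np
import pytest

from dommseq import Sequence, SequenceSet, build_pst, build_spd, extract_patterns
from dommseq.spd import Pattern, Wildcard, pattern_count, pattern_next_count

from conftest import (
    brute_pattern_count,
    corpus_to_set,
    pattern_as_choices,
    random_corpus,
    substring_count,
)


def all_contexts(tree):
    """(context, count) for every concrete-path node, via DFS."""
    out = []

    def walk(node, path):
        if path and all(isinstance(e, str) for e in path):
            out.append((tuple(reversed(path)), node.count))
        for child in node.all_children():
            walk(child, path + [child.element])

    walk(tree.root, [])
    return out


class TestBuildPst:
    def test_small_examples(self):
        T = build_pst(corpus_to_set(["abab"]), L=3)
        ctx = dict(all_contexts(T))
        assert ctx[("a", "b")] == 2
        assert ctx[("b", "a")] == 1
        T2 = build_pst(corpus_to_set(["aaaa"]), L=2)
        ctx2 = dict(all_contexts(T2))
        assert ctx2[("a",)] == 4 and ctx2[("a", "a")] == 3

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            build_pst(corpus_to_set(["ab"]), L=0)

    def test_counts_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            corpus = random_corpus(rng)
            L = int(rng.integers(1, 6))
            T = build_pst(corpus_to_set(corpus), L=L)
            for context, count in all_contexts(T):
                assert count == substring_count(corpus, context), context
                assert len(context) <= L


class TestBuildSpd:
    def test_fig_corpus_tau20(self, fig_corpus):
        T = build_spd(fig_corpus, L=4, tau=20)
        depth4 = [p for p in extract_patterns(T) if len(p) == 4]
        rendered = {str(p): (p.count, p.is_sparse) for p in depth4}
        assert rendered == {
            "GTGT": (25, False),
            "G[SV]GT": (34, True),
            "GT[AI]T": (32, True),
        }

    def test_fig_corpus_tau15_all_consecutive(self, fig_corpus):
        T = build_spd(fig_corpus, L=4, tau=15)
        depth4 = [p for p in extract_patterns(T) if len(p) == 4]
        assert len(depth4) == 5
        assert not any(p.is_sparse for p in depth4)

    def test_huge_tau_prunes_everything(self):
        T = build_spd(corpus_to_set(["abab", "baba"]), L=3, tau=1000)
        assert T.root.is_leaf()
        assert extract_patterns(T) == []

    def test_auto_tau_is_cluster_size(self):
        C = corpus_to_set(["abc", "abc", "abc"])
        assert build_spd(C, L=2, tau="auto").tau == 3.0

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            build_spd(corpus_to_set(["ab"]), L=2, tau=0)

    def test_merged_count_conservation(self, fig_corpus):
        # G[SV]GT must carry exactly the sum of the merged variants
        T = build_spd(fig_corpus, L=4, tau=20)
        gt = T.root.children["T"].children["G"]
        wc = gt.wildcard_child
        assert isinstance(wc.element, Wildcard)
        assert wc.element.subset == frozenset({"S", "V"})
        assert wc.count == 16 + 18

    def test_every_retained_node_meets_tau(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            corpus = random_corpus(rng)
            C = corpus_to_set(corpus)
            tau = int(rng.integers(1, 8))
            T = build_spd(C, L=4, tau=tau)
            for node in T.iter_nodes():
                if node is not T.root:
                    assert node.count >= tau

    def test_monotone_in_tau(self, fig_corpus):
        lo = {str(p) for p in extract_patterns(build_spd(fig_corpus, L=4, tau=15))
              if len(p) == 4}
        hi = {str(p) for p in extract_patterns(build_spd(fig_corpus, L=4, tau=25))
              if len(p) == 4 and not p.is_sparse}
        # consecutive depth-4 survivors at the higher threshold are a subset
        assert hi <= lo


class TestDegenerateEquivalence:
    def test_no_merge_equals_pruned_pst(self):
        # corpus whose sub-threshold nodes vanish entirely: no wildcard arises
        C = corpus_to_set(["abab" * 3] * 4)
        T_spd = build_spd(C, L=3, tau=8)
        assert all(not isinstance(p.element, Wildcard) for p in T_spd.iter_nodes()
                   if p.element is not None)
        spd_ctx = sorted(all_contexts(T_spd))
        T_pruned = build_spd(C, L=3, tau=8, sparse=False)
        assert sorted(all_contexts(T_pruned)) == spd_ctx
        assert {str(p) for p in extract_patterns(T_spd)} == \
               {str(p) for p in extract_patterns(T_pruned)}


class TestExtractPatterns:
    def test_abc_maximal_contexts(self):
        # reversed-context storage: "ab" and "bc" are depth-capped maxima and
        # "a" has no left extension; "c" extends to "bc" so it is not maximal
        T = build_spd(corpus_to_set(["abc"]), L=2, tau=1)
        assert {str(p) for p in extract_patterns(T)} == {"a", "ab", "bc"}

    def test_no_short_pattern_when_extension_survives(self, fig_corpus):
        T = build_spd(fig_corpus, L=4, tau=20)
        names = {str(p) for p in extract_patterns(T)}
        assert "GTGT" in names and "TGT" not in names

    def test_pattern_invariants(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            C = corpus_to_set(random_corpus(rng))
            for p in extract_patterns(build_spd(C, L=4, tau=int(rng.integers(1, 6)))):
                assert isinstance(p.elements[0], str)
                assert isinstance(p.elements[-1], str)
                assert p.count >= 1


class TestPatternCounting:
    def test_wildcard_examples(self):
        from dommseq import Alphabet
        A = Alphabet(("A", "G", "S", "T", "V"))
        theta = Pattern(("G", Wildcard(frozenset({"S", "V"})), "G", "T"))
        S = Sequence("s", tuple("GVGTA"))
        assert pattern_count(theta, S, A) == 1
        assert pattern_next_count(theta, "A", S, A) == 1

    def test_overlapping_occurrences(self):
        C = corpus_to_set(["GTGTGT"])
        theta = Pattern(tuple("GTGT"))
        assert pattern_count(theta, C.sequences[0], C.alphabet) == 2

    def test_wildcard_restricted_to_subset(self):
        C = corpus_to_set(["GTGTC"])
        theta = Pattern(("G", "T", Wildcard(frozenset({"I", "A"})), "T"))
        # needs I/A alphabet members present for encoding
        A = corpus_to_set(["GTGTCIA"]).alphabet
        assert pattern_count(theta, C.sequences[0], A) == 0

    def test_longer_than_sequence(self):
        C = corpus_to_set(["ab"])
        theta = Pattern(tuple("aba"))
        assert pattern_count(theta, C.sequences[0], C.alphabet) == 0

    def test_against_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            corpus = random_corpus(rng, max_seqs=3)
            C = corpus_to_set(corpus)
            A = C.alphabet
            syms = list(A.symbols)
            m = int(rng.integers(1, 5))
            elements = []
            for pos in range(m):
                if 0 < pos < m - 1 and rng.random() < 0.4:
                    size = int(rng.integers(1, len(syms) + 1))
                    elements.append(Wildcard(frozenset(
                        rng.choice(syms, size=size, replace=False))))
                else:
                    elements.append(str(rng.choice(syms)))
            theta = Pattern(tuple(elements))
            got = sum(pattern_count(theta, S, A) for S in C)
            assert got == brute_pattern_count(corpus, pattern_as_choices(theta))

    def test_pattern_rejects_wildcard_ends(self):
        with pytest.raises(ValueError):
            Pattern((Wildcard(frozenset({"a"})), "b"))
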