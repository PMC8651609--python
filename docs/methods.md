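# Methods

## Model

A cluster C of categorical sequences over the alphabet Σ is modeled by the
set Θ of its *longest frequent patterns* — consecutive or sparse — and a
table of conditionals P̂_M(s|θ) for θ ∈ Θ, s ∈ Σ. A sparse pattern masks
one or more interior positions with wildcards; each wildcard carries the
explicit symbol subset V it matches (never the whole alphabet implicitly),
so occurrence counts are sums over concrete instantiations:
n(θ, S) = Σ_{q∈V} n(θ₁ q θ₂, S), counted with overlapping sliding windows
within each sequence (windows never span sequence boundaries).

Per sequence, P̂_S(s|θ) = [n(θs,S)/n(θ,S)] · [n(θ,S)/|S|], which reduces
algebraically to n(θs,S)/|S| and is defined as 0 when θ is absent. The
first factor is the empirical successor probability, the second weights it
by the pattern's frequency in S, so long sequences in which a pattern is
rare are discounted. The cluster conditional minimizing the chi-square
clustering objective is the length-weighted quadratic mean

    P̂_M(s|θ) = sqrt( Σ_{S∈C} |S| · P̂_S(s|θ)² / Σ_{S∈C} |S| ).

The sequence–cluster dissimilarity is

    d(S,C) = (1/|Θ|) Σ_{s∈Σ} Σ_{θ∈Θ} (P̂_S(s|θ) − P̂_M(s|θ))² / max(P̂_M(s|θ), ε),

and the clustering objective (SCError) is Σ_k Σ_{S∈C_k} d(S, C_k).

**Why the 1/|Θ| normalization.** The generative form of the model charges
each sequence position one chi-square term, so dissimilarities to two
different models are on a common scale. Rewriting the sum over positions
as a sum over Θ×Σ cells silently makes the scale proportional to the
model's own pattern count. That interacts badly with the dynamic support
threshold τ = |C|: a cluster that loses members lowers its τ, mines
*more* patterns, accumulates more discrepancy terms for every sequence,
and therefore repels sequences — a positive feedback loop that we
observed collapsing partitions from 93% initial agreement down to a
singleton cluster. Averaging over patterns restores cross-model
comparability; `normalize=False` retains the raw sum. With a single
pattern the two forms coincide.

**Zero handling.** Cells where both probabilities are 0 contribute
nothing; where the model conditional alone is 0, the denominator is
floored at ε = 1e-6, keeping d finite while preserving d(S,C) = 0 iff
P̂_S ≡ P̂_M over Θ×Σ. The generative probability exp(−d) is exposed only
as a convenience (`similarity`); all decisions use d.

## Sparse pattern detector

The detector is a probability suffix tree storing contexts most recent
symbol first: the node for context x has a child for context σx, and a
root-to-node path spells the context right-to-left. Node counts are
overlapping sliding-window totals over the cluster. Construction then
walks the unpruned tree top-down; at each node the children split into
U (count ≥ τ) and V (count < τ). U children are kept and recursed. If V
is non-empty, the V subtrees are merged element-wise — one wildcard child
whose subset is the union of the merged edge symbols and whose node
counts are sums — and the merged subtree survives iff its root count
reaches τ, in which case the same rule recurses inside it (yielding
patterns with several, possibly adjacent, wildcards). Sub-frequent
children are removed either way, so every retained node meets τ. A
single-symbol "wildcard" can only arise with count < τ and is therefore
always discarded; no special case is needed. When no merge triggers the
SPD is exactly a threshold-pruned PST and the model decays to a plain
variable-order Markov model (tested as a property, and exposed as the
consecutive-only ablation via `sparse=False`).

**Pattern extraction.** Θ contains the *maximal valid* patterns: a valid
pattern begins and ends with a concrete symbol (wildcards mask only
interior positions), and a node emits its pattern iff no descendant
spells a valid pattern. Plain leaf-path extraction is not usable here:
whenever every child of a node is sub-frequent, their merged wildcard
inherits nearly the parent's count and survives, so merged wildcard
chains reach the depth cap and every leaf path would begin with a
wildcard, leaving Θ empty. Trimming to the deepest valid node resolves
this; it also decides, in favor of maximality, whether shorter patterns
should be kept when only wildcard extensions survive.

**Thresholds.** τ defaults to the number of sequences in the cluster
(a frequent pattern should occur about once per member) and is recomputed
every refinement iteration as cluster sizes change; a numeric override
exists for worked examples. The maximal depth L defaults to 10;
experiments below use L = 6, one more than needed for their motif
structure.

## Vectorization and initialization

Each sequence maps to its Markov Vector of Sequence (MVS): the symbol
frequency vector V_F, the transition occurrence matrix M_O, the
Bayesian-smoothed transition matrix M_P with
p_ij = (η_ij/η_i)·(η_i/(η_i+O_i)) + O_ij/(η_i+O_i), η_ij = 1/|Σ|
(a Dirichlet-style shrinkage toward uniform — empty rows map to 1/|Σ|,
large rows converge to the empirical estimate), the weighted matrix
M_FP = diag(V_F)·M_P, and its row-major flattening (length |Σ|², entries
sum to 1). The hyper-parameters are fixed at the stated values and not
exposed as user knobs.

A split bisects the selected cluster's MVS rows on the sign of the first
principal component (mean-centered SVD; the component's sign is fixed by
making its largest-magnitude loading positive; zero scores go to the
second side), then refines the two sides by alternating chi-square
assignment, χ²(x,c) = Σ_i (x_i−c_i)²/(x_i+c_i) over coordinates with
positive denominator, against coordinate-mean centroids until stable.
The refinement operates on the **raw MVS rows** by default: the
chi-square distance is a histogram distance and the MVS is a proper
non-negative histogram over symbol pairs, whereas on signed PCA scores
most coordinate pairs fail the positivity guard and the refinement
degraded a perfect bisection to near-chance in our tests. PCA-reduced
coordinates (components covering `variance_kept` = 95% of variance)
remain available via `chi_coords="pca"`.

The cluster chosen for bisection is the one contributing the most
clustering error Σ_{S∈C} d(S,C) — the *least* compact cluster; splitting
the tightest cluster would be self-defeating and contradicts bisecting
practice. The literal opposite is available via
`split_mode="max_compactness"`. Ties prefer the larger cluster;
singletons and clusters with identical MVS rows are never selected.

After initialization the two clusters are refined by the DOMM optimizer:
rebuild SPDs (τ = current sizes), refit models, reassign every sequence
to the cluster of minimal d (ties keep the current membership), iterate
until no change or `max_iter` = 100. A cluster is never allowed to empty:
the sequence farthest from the surviving model is retained. The whole
algorithm is deterministic given the input order; the `seed` argument
only drives the synthetic generator.

## Evaluation metrics

Accuracy is the matched fraction after an optimal one-to-one
predicted→true assignment (Hungarian algorithm on the contingency
table). F1 uses set-matching precision |C∩G|/|C| and recall |C∩G|/|G|
per matched pair; the matching maximizes the class-size-weighted mean F1
itself, which keeps the score invariant under relabeling even when
several matchings tie on matched counts (a macro average is available).
NMI is 2·I(C,G)/(H(C)+H(G)) in natural log (the base cancels), with the
0/0 case of two single-class partitions defined as 1.

## Synthetic benchmark

`two_class_benchmark()` is the canonical test bed: 2 classes × 50
sequences of length 200 over Σ = {a,b,c,d}. Each class draws from a
first-order chain mixing a uniform background with one of the two
directed 4-cycles at weight 0.08 — enough for the MVS initialization to
be informative (~85–95% agreement) but not to separate the classes on
its own. Every sequence then receives exactly two copies of each of
three class-specific length-7 motifs, written over the chain backbone at
non-overlapping uniform positions:

    head · noisy position · shared 4-symbol core · shared tail

The noisy position draws uniformly from a class-specific 3-symbol
subset. The geometry is chosen so that the discriminative content is
reachable only through sparse mining at τ = cluster size (50): each
concrete variant occurs ≈ 2·50/3 ≈ 33 < τ times while the masked form
occurs ≈ 100 ≥ τ times, and the consecutive fragments a plain PST can
mine (the core and tail) are shared between the classes and therefore
carry no class signal. Deterministic copy number mirrors the
near-constant domain copy number of protein families and keeps
per-sequence pattern frequencies concentrated — with Poisson insertion
counts the quadratic-mean conditional sits visibly above the typical
per-sequence value and in-class sequences mismatch their own model
almost as much as out-class ones. The motif extending one symbol past
the mined depth (length 7 vs L = 6) makes each pattern's successor
symbol deterministic, concentrating its evidence in a single cell of the
conditional table.

At these frozen conditions (seeds 1–10, fully deterministic) divisive
clustering with sparse patterns attains mean accuracy 0.949 and mean NMI
0.729, and the consecutive-only ablation is strictly lower on 8 of 10
seeds (mean 0.934 / 0.659) — a qualitative mirror of the ablation gap
the method is designed to demonstrate. The generator emulates labeled
cluster structure, first-order dependence and noise-masked motifs; it
does not emulate alignment-scale homology, indels within motifs,
length/composition confounds, or alphabet sizes beyond those configured,
so passing recovery tests demonstrates the mechanism, not performance on
real biological corpora.

## Numerical choices and limitations

* Flattening order, symbol order, and pattern/tie orders are all fixed
  (alphabet order, input order), making every run reproducible
  byte-for-byte.
* The dissimilarity floor ε, the 1/|Θ| normalization, the raw-MVS
  chi-square default and the max-error split rule are the four places
  where the design was genuinely open; each is switchable and the
  defaults are justified above.
* Worst-case SPD size grows with corpus size × L; on small alphabets the
  sub-frequent merge can cascade (wildcard chains down to depth L),
  which extraction handles but which costs memory — large corpora should
  lower L.
* The optimizer greedily reassigns against refitted models; SCError
  decreases empirically on most instances but no monotone-convergence
  guarantee exists, hence the iteration cap.
* K must be supplied; no model selection is attempted.
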