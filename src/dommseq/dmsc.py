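"""Divisive clustering of categorical sequences (DMSC).

The driver vectorizes every sequence once (MVS), then grows the
partition one cluster at a time until K clusters exist.  Each split:

1. pick the cluster with the largest clustering-error contribution
   Σ_{S∈C} d(S,C) (ties broken toward the larger cluster);
2. bisect its MVS rows on the sign of the first principal component;
3. refine the two sides by alternating chi-square-distance assignment
   on PCA-reduced coordinates;
4. refine again with the DOMM optimizer: rebuild an SPD per cluster
   (τ = current cluster size), fit models, reassign every sequence to
   the cluster of minimal dissimilarity, iterate to convergence.

The whole procedure is deterministic given the input order; randomness
enters only through the synthetic data generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .domm import ClusterModel, dissim, fit_model, sc_error
from .mvs import vectorize_set
from .seqio import SequenceSet
from .spd import build_spd, extract_patterns

logger = logging.getLogger("dommseq")


@dataclass
class ClusteringResult:
    assignments: np.ndarray            # cluster id per input sequence
    clusters: list[SequenceSet]
    models: list[ClusterModel]
    sc_error: float
    history: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Initialization: PCA bisection + chi-square refinement
# ---------------------------------------------------------------------------

def bisect_pca(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split rows of an MVS matrix on the sign of the first principal component.

    Columns are mean-centered; the PC sign is fixed so the largest-magnitude
    loading is positive.  Rows with strictly positive score go to the first
    side, the rest (including zero scores) to the second.
    """
    V = np.asarray(V, dtype=float)
    if V.shape[0] < 2:
        raise ValueError("need at least 2 rows to bisect")
    X = V - V.mean(axis=0)
    if not np.any(X):
        raise ValueError("degenerate cluster, cannot bisect (all rows identical)")
    # PC1 via SVD of the centered matrix (deterministic)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    pc1 = Vt[0]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    scores = X @ pc1
    side1 = np.flatnonzero(scores > 0)
    side2 = np.flatnonzero(scores <= 0)
    if len(side1) == 0 or len(side2) == 0:
        # numerically one-sided scores: split at the median instead
        order = np.argsort(scores, kind="stable")
        half = len(order) // 2
        side1, side2 = np.sort(order[half:]), np.sort(order[:half])
    return side1, side2


def pca_reduce(V: np.ndarray, variance_kept: float = 0.95) -> np.ndarray:
    """Project mean-centered rows onto the components explaining the given variance."""
    X = np.asarray(V, dtype=float)
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.sum() == 0:
        return X[:, :1]
    var = s**2
    frac = np.cumsum(var) / var.sum()
    m = int(np.searchsorted(frac, variance_kept) + 1)
    return U[:, :m] * s[:m]


def chi_square_distance(x: np.ndarray, c: np.ndarray) -> float:
    """χ²(x,c) = Σ_i (x_i−c_i)²/(x_i+c_i) over coordinates with x_i+c_i > 0."""
    denom = x + c
    mask = denom > 0
    if not np.any(mask):
        return 0.0
    return float(((x[mask] - c[mask]) ** 2 / denom[mask]).sum())


def chi_square_refine(
    split: tuple[np.ndarray, np.ndarray],
    V: np.ndarray,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating assignment / mean-centroid update under chi-square distance.

    Stops when assignments are stable or ``max_iter`` is reached.  A side
    is never allowed to empty: if it would, its farthest-from-the-other-
    centroid point is kept.
    """
    side1, side2 = (np.asarray(s, dtype=np.int64) for s in split)
    if len(side1) == 0 or len(side2) == 0:
        raise ValueError("both sides must be non-empty")
    V = np.asarray(V, dtype=float)
    n = V.shape[0]
    assign = np.zeros(n, dtype=np.int64)
    assign[side2] = 1
    for _ in range(max_iter):
        c0 = V[assign == 0].mean(axis=0)
        c1 = V[assign == 1].mean(axis=0)
        d0 = np.array([chi_square_distance(V[i], c0) for i in range(n)])
        d1 = np.array([chi_square_distance(V[i], c1) for i in range(n)])
        new = np.where(d0 <= d1, 0, 1)
        for side, dist in ((0, d1), (1, d0)):
            if not np.any(new == side):
                # keep the point farthest from the opposite centroid
                new[int(np.argmax(dist))] = side
        if np.array_equal(new, assign):
            break
        assign = new
    return np.flatnonzero(assign == 0), np.flatnonzero(assign == 1)


# ---------------------------------------------------------------------------
# DOMM clustering optimizer
# ---------------------------------------------------------------------------

def _fit_cluster(C: SequenceSet, L: int, tau_override: float | None,
                 sparse: bool) -> ClusterModel:
    tau = "auto" if tau_override is None else tau_override
    tree = build_spd(C, L=L, tau=tau, sparse=sparse)
    theta = extract_patterns(tree)
    return fit_model(C, theta, tau=tree.tau)


def optimize_clusters(
    C1: SequenceSet,
    C2: SequenceSet,
    L: int = 10,
    max_iter: int = 100,
    sparse: bool = True,
    tau_override: float | None = None,
    epsilon: float = 1e-6,
) -> tuple[SequenceSet, SequenceSet, list[ClusterModel], int, np.ndarray]:
    """Iterative model-fit / reassignment refinement of a two-way split.

    Per iteration an SPD is rebuilt on each cluster (τ follows the current
    cluster size), models are refitted, and every sequence moves to the
    cluster of minimal dissimilarity (ties keep it where it is).  Neither
    cluster may empty: the sequence farthest from the surviving model is
    retained.  Returns the refined clusters, their models, the number of
    iterations used, and the final side assignment in the concatenated
    (C1 then C2) input order.
    """
    parent = SequenceSet(
        list(C1.sequences) + list(C2.sequences),
        labels=(C1.labels + C2.labels) if C1.labels is not None and C2.labels is not None else None,
        alphabet=C1.alphabet,
    )
    n = parent.N
    assign = np.zeros(n, dtype=np.int64)
    assign[C1.N:] = 1
    models: list[ClusterModel] = []
    iters = 0
    for iters in range(1, max_iter + 1):
        sub = [parent.subset(np.flatnonzero(assign == g)) for g in (0, 1)]
        models = [_fit_cluster(c, L, tau_override, sparse) for c in sub]
        d = np.empty((n, 2))
        for g, M in enumerate(models):
            for i, S in enumerate(parent):
                d[i, g] = dissim(S, M, epsilon)
        new = np.where(d[:, 0] < d[:, 1], 0, np.where(d[:, 1] < d[:, 0], 1, assign))
        for g in (0, 1):
            if not np.any(new == g):
                other = models[1 - g]
                far = np.array([dissim(S, other, epsilon) for S in parent])
                new[int(np.argmax(far))] = g
        if np.array_equal(new, assign):
            break
        assign = new
    out1 = parent.subset(np.flatnonzero(assign == 0))
    out2 = parent.subset(np.flatnonzero(assign == 1))
    return out1, out2, models, iters, assign


# ---------------------------------------------------------------------------
# Split selection and the top-level driver
# ---------------------------------------------------------------------------

def cluster_error(C: SequenceSet, M: ClusterModel, epsilon: float = 1e-6) -> float:
    """This cluster's contribution Σ_{S∈C} d(S,C) to the SCError objective."""
    return sum(dissim(S, M, epsilon) for S in C)


def select_cluster_to_split(
    clusters: list[SequenceSet],
    models: list[ClusterModel],
    mvs_rows: list[np.ndarray],
    mode: str = "max_error",
    epsilon: float = 1e-6,
) -> int:
    """Index of the next cluster to bisect.

    ``max_error`` (default) picks the least compact cluster — the one
    with the largest SCError contribution; ``max_compactness`` picks the
    literal opposite.  Ties go to the larger cluster.  Singleton or
    degenerate clusters (identical MVS rows) are never selected.
    """
    candidates = []
    for i, (C, rows) in enumerate(zip(clusters, mvs_rows)):
        if C.N < 2:
            continue
        if np.allclose(rows, rows[0]):
            continue
        candidates.append(i)
    if not candidates:
        raise ValueError("no splittable cluster (all singleton or degenerate)")
    errors = {i: cluster_error(clusters[i], models[i], epsilon) for i in candidates}
    sign = 1.0 if mode == "max_error" else -1.0
    return max(candidates, key=lambda i: (sign * errors[i], clusters[i].N))


def dmsc(
    data: SequenceSet,
    K: int,
    L: int = 10,
    seed: int = 0,
    max_iter: int = 100,
    sparse: bool = True,
    tau_override: float | None = None,
    epsilon: float = 1e-6,
    variance_kept: float = 0.95,
    split_mode: str = "max_error",
    chi_coords: str = "mvs",
) -> ClusteringResult:
    """Divisive DOMM clustering of ``data`` into K clusters.

    ``sparse=False`` runs the consecutive-pattern-only ablation.
    ``chi_coords`` selects the coordinates for chi-square refinement:
    ``"mvs"`` (default) uses the raw non-negative MVS rows, on which the
    chi-square distance is a proper histogram distance; ``"pca"`` uses
    PCA-reduced coordinates retaining ``variance_kept`` of the variance.
    The algorithm itself is deterministic; ``seed`` is accepted for
    interface symmetry with the generator and ignored.
    """
    del seed  # deterministic given the input order
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > data.N:
        raise ValueError(f"K={K} exceeds the number of sequences N={data.N}")

    V = vectorize_set(data)
    index_sets: list[np.ndarray] = [np.arange(data.N)]
    history: list[dict] = []

    while len(index_sets) < K:
        clusters = [data.subset(idx) for idx in index_sets]
        models = [_fit_cluster(c, L, tau_override, sparse) for c in clusters]
        pick = select_cluster_to_split(
            clusters, models, [V[idx] for idx in index_sets],
            mode=split_mode, epsilon=epsilon,
        )
        idx = index_sets[pick]
        rows = V[idx]
        side1, side2 = bisect_pca(rows)
        coords = rows if chi_coords == "mvs" else pca_reduce(rows, variance_kept)
        side1, side2 = chi_square_refine((side1, side2), coords, max_iter=max_iter)
        c1 = data.subset(idx[side1])
        c2 = data.subset(idx[side2])
        _, _, _, iters, side_assign = optimize_clusters(
            c1, c2, L=L, max_iter=max_iter, sparse=sparse,
            tau_override=tau_override, epsilon=epsilon,
        )
        concat = np.concatenate([idx[side1], idx[side2]])
        new1 = np.sort(concat[side_assign == 0])
        new2 = np.sort(concat[side_assign == 1])
        index_sets[pick] = new1
        index_sets.append(new2)
        history.append({"split_cluster": pick, "iterations": iters,
                        "sizes": (len(new1), len(new2))})
        logger.info("split cluster %d into sizes %d/%d after %d iterations",
                    pick, len(new1), len(new2), iters)

    clusters = [data.subset(idx) for idx in index_sets]
    models = [_fit_cluster(c, L, tau_override, sparse) for c in clusters]
    assignments = np.empty(data.N, dtype=np.int64)
    for cid, idx in enumerate(index_sets):
        assignments[idx] = cid
    err = sc_error(list(zip(clusters, models)), epsilon)
    logger.info("final SCError = %.6g over %d clusters", err, K)
    return ClusteringResult(
        assignments=assignments, clusters=clusters, models=models,
        sc_error=err, history=history,
    )
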