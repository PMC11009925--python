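"""Label-switching resolution and posterior summarisation.

A mixture likelihood is invariant to relabelling its classes, so raw MCMC
output scrambles class-specific summaries. The pipeline here works from the
label-free posterior co-clustering (similarity) matrix:

1. :func:`select_n_classes` — posterior-mode count of classes holding at
   least 5% of subjects;
2. :func:`coclustering_matrix` + :func:`consensus_clusters` — complete-
   linkage hierarchical clustering of ``1 - S`` cut at that count;
3. :func:`relabel_draws` — per-iteration optimal assignment of sampled
   classes to the consensus groups;
4. :func:`summarize` — posterior medians of prevalence, mean/median
   item-response probabilities, modal patterns and final assignments.

Every downstream summary is invariant to arbitrary per-iteration label
permutations of the input draws, which is the point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .data_model import PosteriorDraws

__all__ = [
    "CoClusteringMatrix",
    "ClassSummary",
    "RelabelledDraws",
    "coclustering_matrix",
    "consensus_clusters",
    "select_n_classes",
    "relabel_draws",
    "summarize",
    "postprocess_draws",
    "psrf",
]

EXISTENCE_THRESHOLD = 0.05  # a class is "real" if it holds >= 5% of subjects


@dataclass
class CoClusteringMatrix:
    """``S[a, b]`` = fraction of retained iterations assigning subjects a and
    b to the same class. Symmetric, unit diagonal, label-free."""

    S: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=np.float64)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        self.S = S

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass
class RelabelledDraws:
    """Draws with per-iteration labels aligned to a consensus partition.

    ``z_draws`` uses 0 for subjects whose iteration-specific class was not
    matched to any consensus group; ``discard_mass[t]`` is the prevalence
    mass of those surplus classes at iteration t.
    """

    pi_draws: np.ndarray  # (T, G)
    theta_draws: np.ndarray  # (T, p, d_max, G)
    z_draws: np.ndarray  # (T, n), 1-based, 0 = unassigned
    discard_mass: np.ndarray  # (T,)
    consensus: np.ndarray  # (n,), 1-based
    level_counts: np.ndarray

    @property
    def T(self) -> int:
        return self.pi_draws.shape[0]

    @property
    def n_classes(self) -> int:
        return self.pi_draws.shape[1]


@dataclass
class ClassSummary:
    """Posterior summary of the surviving latent classes."""

    n_classes: int
    prevalence: np.ndarray  # (G,) posterior median pi
    theta_mean: np.ndarray  # (p, d_max, G)
    theta_median: np.ndarray  # (p, d_max, G)
    modal_pattern: np.ndarray  # (G, p), 1-based levels
    assignments: np.ndarray  # (n,), 1-based consensus labels
    discard_mass_mean: float = 0.0


def coclustering_matrix(z_draws: np.ndarray) -> CoClusteringMatrix:
    """Posterior similarity matrix ``S_ab = (1/T) sum_t 1(z_a^t = z_b^t)``."""
    z = np.asarray(z_draws)
    if z.ndim != 2 or z.shape[0] < 1:
        raise ValueError("need at least one retained iteration of z draws")
    T, n = z.shape
    S = np.zeros((n, n), dtype=np.float64)
    # sum over classes of H_k^T H_k with H_k the (T, n) indicator of class k
    for k in np.unique(z):
        H = (z == k).astype(np.float32)
        S += (H.T @ H).astype(np.float64)
    S /= T
    np.fill_diagonal(S, 1.0)
    return CoClusteringMatrix(S)


def consensus_clusters(S: CoClusteringMatrix, n_classes: int) -> np.ndarray:
    """Complete-linkage agglomerative clustering on dissimilarity ``1 - S``,
    cut to exactly ``n_classes`` groups by merge order (the ``cutree``
    semantics). Cutting by merge order rather than by a height threshold
    matters: with a finite number of retained draws many subject pairs
    never co-cluster, so the top of the dendrogram is full of ties at
    distance exactly 1 and no height threshold yields the requested count.
    Deterministic given S (scipy's linkage breaks merge ties by observation
    order). Returns 1-based labels, renumbered by first appearance."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    n = S.n
    if n_classes > n:
        raise ValueError(f"cannot form {n_classes} clusters from {n} subjects")
    if n_classes == 1:
        return np.ones(n, dtype=np.int64)
    D = 1.0 - S.S
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="complete")
    labels = cut_tree(Z, n_clusters=n_classes).ravel() + 1
    # renumber by first appearance so labelling is order-canonical
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=np.int64)


def _existing_class_count(z_t: np.ndarray, n: int, K: int, threshold: float) -> int:
    occ = np.bincount(z_t.astype(np.int64), minlength=K + 1)[1:] / n
    return int(np.sum(occ >= threshold))


def select_n_classes(
    pi_draws: np.ndarray,
    z_draws: np.ndarray,
    threshold: float = EXISTENCE_THRESHOLD,
) -> int:
    """Posterior-mode number of classes holding at least ``threshold`` of the
    sampled subjects (unweighted occupancy; the boundary counts as existing).
    Ties in the mode go to the smaller count."""
    z = np.asarray(z_draws)
    if z.ndim != 2 or z.shape[0] < 1:
        raise ValueError("draws must be nonempty")
    T, n = z.shape
    K = pi_draws.shape[1]
    counts = np.array(
        [_existing_class_count(z[t], n, K, threshold) for t in range(T)]
    )
    freq = np.bincount(counts)
    return int(np.argmax(freq))


def relabel_draws(draws: PosteriorDraws, consensus: np.ndarray) -> RelabelledDraws:
    """Align every iteration's class labels with the consensus partition.

    For each retained iteration, build the contingency table between the
    iteration's K classes and the G consensus groups and solve the optimal
    assignment (maximum overlap, Hungarian algorithm). Matched classes take
    the consensus label; surplus classes go to a discard bucket whose
    prevalence mass is recorded.
    """
    consensus = np.asarray(consensus, dtype=np.int64)
    G = int(consensus.max())
    T, K = draws.pi_draws.shape
    n = draws.n
    p, d_max = draws.theta_draws.shape[1], draws.theta_draws.shape[2]

    pi_new = np.zeros((T, G))
    theta_new = np.zeros((T, p, d_max, G), dtype=draws.theta_draws.dtype)
    z_new = np.zeros((T, n), dtype=np.int64)
    discard = np.zeros(T)
    cons0 = consensus - 1

    for t in range(T):
        z_t = draws.z_draws[t].astype(np.int64) - 1
        # overlap[k, g] = #subjects in sampled class k and consensus group g
        overlap = np.zeros((K, G), dtype=np.int64)
        np.add.at(overlap, (z_t, cons0), 1)
        rows, cols = linear_sum_assignment(-overlap)
        matched = np.full(K, -1, dtype=np.int64)
        matched[rows] = cols
        for k, g in zip(rows, cols):
            pi_new[t, g] = draws.pi_draws[t, k]
            theta_new[t, :, :, g] = draws.theta_draws[t, :, :, k]
        assigned = matched[z_t]
        z_new[t] = np.where(assigned >= 0, assigned + 1, 0)
        discard[t] = 1.0 - pi_new[t].sum()

    return RelabelledDraws(
        pi_draws=pi_new,
        theta_draws=theta_new,
        z_draws=z_new,
        discard_mass=np.clip(discard, 0.0, None),
        consensus=consensus,
        level_counts=draws.level_counts.copy(),
    )


def summarize(
    relabelled: RelabelledDraws,
    coclustering: CoClusteringMatrix | None = None,
    threshold: float = EXISTENCE_THRESHOLD,
) -> ClassSummary:
    """Posterior summaries of the aligned draws.

    Classes whose posterior-median prevalence falls below ``threshold`` are
    dropped; their subjects are reassigned to the surviving class with the
    highest mean co-clustering affinity (requires ``coclustering`` when a
    drop occurs). Modal patterns are the argmax over levels of the posterior
    mean ``theta`` (ties break to the lower level).
    """
    prev = np.median(relabelled.pi_draws, axis=0)
    keep = prev >= threshold
    if not np.any(keep):
        raise ValueError("no class survives the existence threshold")
    keep_idx = np.flatnonzero(keep)
    G = keep_idx.size

    theta_mean = relabelled.theta_draws[:, :, :, keep_idx].mean(axis=0, dtype=np.float64)
    theta_median = np.median(
        relabelled.theta_draws[:, :, :, keep_idx].astype(np.float64), axis=0
    )
    modal = np.argmax(theta_mean, axis=1).T + 1  # (G, p)

    assignments = relabelled.consensus.copy()
    old_to_new = {old + 1: new + 1 for new, old in enumerate(keep_idx)}
    dropped_subjects = ~np.isin(assignments, list(old_to_new))
    if np.any(dropped_subjects):
        if coclustering is None:
            raise ValueError(
                "coclustering matrix needed to reassign subjects of dropped classes"
            )
        S = coclustering.S
        for i in np.flatnonzero(dropped_subjects):
            affinities = [
                S[i, (assignments == old + 1) & ~dropped_subjects].mean()
                if np.any((assignments == old + 1) & ~dropped_subjects)
                else -np.inf
                for old in keep_idx
            ]
            assignments[i] = keep_idx[int(np.argmax(affinities))] + 1
    assignments = np.array([old_to_new[a] for a in assignments], dtype=np.int64)

    return ClassSummary(
        n_classes=G,
        prevalence=prev[keep_idx],
        theta_mean=theta_mean,
        theta_median=theta_median,
        modal_pattern=modal,
        assignments=assignments,
        discard_mass_mean=float(relabelled.discard_mass.mean()),
    )


def postprocess_draws(
    draws: PosteriorDraws, threshold: float = EXISTENCE_THRESHOLD
) -> tuple[ClassSummary, RelabelledDraws, CoClusteringMatrix]:
    """Full pipeline: class-count selection, co-clustering, consensus,
    relabelling, summary."""
    G = select_n_classes(draws.pi_draws, draws.z_draws, threshold)
    G = max(G, 1)
    S = coclustering_matrix(draws.z_draws)
    consensus = consensus_clusters(S, G)
    relabelled = relabel_draws(draws, consensus)
    summary = summarize(relabelled, coclustering=S, threshold=threshold)
    return summary, relabelled, S


def psrf(chains: np.ndarray | list) -> float:
    """Gelman–Rubin potential scale reduction factor for one scalar
    parameter traced by ``m >= 2`` chains of common length ``L``:

    ``sqrt( ((L-1)/L * W + B/L) / W )``

    with ``W`` the mean within-chain variance and ``B`` the between-chain
    variance of the chain means scaled by ``L``. Values near 1 indicate
    convergence. Zero within-chain variance yields NaN with a warning.
    """
    X = np.asarray(chains, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 4:
        raise ValueError("need >= 2 chains of length >= 4")
    m, L = X.shape
    W = X.var(axis=1, ddof=1).mean()
    B = L * X.mean(axis=1).var(ddof=1)
    if W == 0:
        warnings.warn("zero within-chain variance; PSRF undefined", stacklevel=2)
        return float("nan")
    var_plus = (L - 1) / L * W + B / L
    return float(np.sqrt(var_plus / W))
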