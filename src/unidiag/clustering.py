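"""Exemplar-based patient clustering via affinity propagation.

Affinity propagation (AP) picks actual patients as cluster exemplars by
responsibility/availability message passing; the number of clusters is
controlled by the shared preference placed on the similarity diagonal:

    p = median(S_offdiag) − p_coe · N

with more negative preferences yielding fewer clusters. The message passing
itself is delegated to scikit-learn's Frey–Dueck implementation (damping,
convergence window, and a seeded symmetry-breaking jitter are exposed here).

Two quality summaries accompany the partition: per-cluster support |C_k|/N
and the sum of member-to-exemplar similarities (SS), larger being better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import affinity_propagation
from sklearn.exceptions import ConvergenceWarning

from .similarity import SimilarityMatrix


@dataclass
class ClusteringResult:
    ids: list[str]
    labels: np.ndarray  # patient index -> cluster index
    exemplar_indices: list[int]  # cluster index -> patient index
    p: float
    n_iter: int
    converged: bool
    supports: np.ndarray = field(init=False)
    K: int = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.K = len(self.exemplar_indices)
        counts = np.bincount(self.labels, minlength=self.K)
        self.supports = counts / len(self.ids)
        for k, e in enumerate(self.exemplar_indices):
            if self.labels[e] != k:
                raise ValueError("exemplar not labeled with its own cluster")

    @property
    def exemplar_ids(self) -> list[str]:
        return [self.ids[e] for e in self.exemplar_indices]

    def members_of(self, k: int) -> list[str]:
        self._check_k(k)
        return [self.ids[i] for i in np.flatnonzero(self.labels == k)]

    def _check_k(self, k: int) -> None:
        if not 0 <= k < self.K:
            raise ValueError(f"cluster index {k} out of range 0..{self.K - 1}")


def preference(S: SimilarityMatrix, p_coe: float) -> float:
    """Exemplar preference p = median of off-diagonal similarities − p_coe·N."""
    if S.n < 2:
        raise ValueError("need at least two patients")
    if p_coe < 0:
        raise ValueError("p_coe must be non-negative")
    off = S.values[~np.eye(S.n, dtype=bool)]
    return float(np.median(off) - p_coe * S.n)


def cluster(
    S: SimilarityMatrix,
    p: float | None = None,
    p_coe: float = 0.025,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_window: int = 50,
    seed: int = 0,
) -> ClusteringResult:
    """Run affinity propagation on a precomputed similarity matrix.

    ``p`` may be supplied directly (for preference sweeps); otherwise it is
    derived from ``p_coe``. Identical inputs and seed give identical labels;
    the seed keys only the tiny jitter that breaks exact similarity ties.
    """
    if not 0.5 <= damping < 1:
        raise ValueError("damping must lie in [0.5, 1)")
    if p is None:
        p = preference(S, p_coe)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        centers, labels, n_iter = affinity_propagation(
            S.values,
            preference=p,
            damping=damping,
            max_iter=max_iter,
            convergence_iter=convergence_window,
            copy=True,
            random_state=seed,
            return_n_iter=True,
        )
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if len(centers) == 0 or (np.asarray(labels) < 0).any():
        # degenerate non-convergence: fall back to one cluster around the
        # patient with the largest total similarity
        warnings.warn(
            "affinity propagation did not converge to a valid exemplar set; "
            "returning a single cluster around the max-row-sum medoid",
            stacklevel=2,
        )
        medoid = int(np.argmax(S.values.sum(axis=0)))
        return ClusteringResult(
            ids=list(S.ids),
            labels=np.zeros(S.n, dtype=int),
            exemplar_indices=[medoid],
            p=float(p),
            n_iter=int(n_iter),
            converged=False,
        )
    result = ClusteringResult(
        ids=list(S.ids),
        labels=np.asarray(labels, dtype=int),
        exemplar_indices=[int(c) for c in centers],
        p=float(p),
        n_iter=int(n_iter),
        converged=converged,
    )
    if not converged:
        warnings.warn(
            f"affinity propagation did not converge within {max_iter} iterations",
            stacklevel=2,
        )
    return result


def support(result: ClusteringResult, k: int) -> float:
    """Fraction of patients assigned to cluster k."""
    result._check_k(k)
    return float(result.supports[k])


def sum_of_similarities(S: SimilarityMatrix, result: ClusteringResult) -> float:
    """SS = Σ over clusters of member-to-exemplar similarity (exemplars add 1)."""
    exemplars = np.asarray(result.exemplar_indices)
    return float(S.values[np.arange(S.n), exemplars[result.labels]].sum())


def sweep_preference(
    S: SimilarityMatrix,
    p_coe_values,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_window: int = 50,
    seed: int = 0,
) -> dict[float, ClusteringResult]:
    """Cluster once per preference coefficient (cluster-count stability sweeps)."""
    return {
        float(p_coe): cluster(
            S,
            p_coe=float(p_coe),
            damping=damping,
            max_iter=max_iter,
            convergence_window=convergence_window,
            seed=seed,
        )
        for p_coe in p_coe_values
    }
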