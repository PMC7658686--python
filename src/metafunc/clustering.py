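"""PCA and PAM (k-medoids) clustering of functional profiles.

The unsupervised view of the cohort: project relative-abundance profiles
onto principal components, cluster samples with partitioning around medoids
(BUILD + SWAP), and cross-tabulate clusters against study groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io_core import FunctionalProfile


@dataclass
class PcaResult:
    scores: pd.DataFrame  # sample x component
    explained_fraction: np.ndarray  # per-component fraction of total variance

    def components_for_variance(self, threshold: float = 0.95) -> int:
        """Smallest number of leading components explaining >= threshold."""
        cum = np.cumsum(self.explained_fraction)
        idx = int(np.searchsorted(cum, threshold - 1e-12)) + 1
        return min(idx, len(self.explained_fraction))


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-sample cluster index in 1..k
    medoids: np.ndarray  # k sample indices, medoid i anchors cluster i+1
    objective: float  # total dissimilarity of samples to their medoid


def pca(profile: FunctionalProfile, n_components: int | None = None) -> PcaResult:
    """Principal components of the (column-centered) abundance matrix."""
    x = profile.data.to_numpy(dtype=float)
    n, m = x.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_comp = min(n - 1, m)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_functions)={max_comp}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        pd.DataFrame(scores, index=profile.data.index, columns=cols),
        model.explained_variance_ratio_,
    )


def _check_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    if (d < -1e-12).any():
        raise ValueError("dissimilarity matrix must be non-negative")
    return d


def pam_cluster(d: np.ndarray, k: int, seed: int = 0) -> ClusterAssignment:
    """Partitioning around medoids: greedy BUILD then SWAP to a local optimum.

    BUILD seeds medoids greedily (each new medoid maximizes the drop in
    total dissimilarity); SWAP repeatedly applies the best improving
    medoid/non-medoid exchange until none lowers the objective, so the
    result is 1-swap-optimal. Ties break on the lexicographically smallest
    (medoid index, candidate index) pair; the procedure is deterministic
    and ``seed`` is accepted only for interface uniformity.
    """
    d = _check_dissimilarity(d)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        best_gain, best_cand = -np.inf, None
        for h in range(n):
            if h in medoids:
                continue
            gain = np.maximum(current - d[:, h], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_cand = gain, h
        medoids.append(best_cand)
    medoids = sorted(medoids)

    def objective(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    # SWAP: best-improvement local search
    obj = objective(medoids)
    while True:
        best = (0.0, None, None)
        for m in sorted(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = [x for x in medoids if x != m] + [h]
                delta = objective(trial) - obj
                if delta < best[0] - 1e-12:
                    best = (delta, m, h)
        if best[1] is None:
            break
        medoids = sorted(x for x in medoids if x != best[1]) + [best[2]]
        medoids = sorted(medoids)
        obj = objective(medoids)

    assign = np.argmin(d[:, medoids], axis=1)
    labels = assign + 1
    # medoid must sit in its own cluster even under distance ties
    for i, m in enumerate(medoids):
        labels[m] = i + 1
    return ClusterAssignment(labels=labels, medoids=np.array(medoids), objective=obj)


def pam_on_profile(
    profile: FunctionalProfile,
    k: int = 3,
    *,
    variance_threshold: float = 0.95,
    use_pca: bool = True,
    seed: int = 0,
) -> tuple[ClusterAssignment, PcaResult]:
    """Cluster samples with PAM on PCA scores retaining >= 95% variance.

    ``use_pca=False`` clusters on the raw relative-abundance matrix instead.
    Returns the assignment and the PCA result (computed either way, for
    score plots).
    """
    result = pca(profile)
    if use_pca:
        ncomp = result.components_for_variance(variance_threshold)
        x = result.scores.to_numpy()[:, :ncomp]
    else:
        x = profile.data.to_numpy(dtype=float)
    d = squareform(pdist(x, metric="euclidean"))
    return pam_cluster(d, k, seed), result


def silhouette_scan(
    profile: FunctionalProfile, k_range=range(2, 9), *, seed: int = 0
) -> pd.Series:
    """Mean silhouette width of the PAM solution for each candidate k."""
    result = pca(profile)
    ncomp = result.components_for_variance()
    x = result.scores.to_numpy()[:, :ncomp]
    d = squareform(pdist(x, metric="euclidean"))
    widths = {}
    for k in k_range:
        if k >= x.shape[0]:
            continue
        labels = pam_cluster(d, k, seed).labels
        widths[k] = float(silhouette_score(d, labels, metric="precomputed"))
    return pd.Series(widths, name="silhouette")


def cluster_group_crosstab(
    assignment: ClusterAssignment, groups
) -> pd.DataFrame:
    """Cluster x study-group contingency table of sample counts."""
    groups = pd.Series(list(groups))
    if len(groups) != len(assignment.labels):
        raise ValueError("cluster labels and group labels differ in length")
    clusters = pd.Series(
        [f"Cluster {i}" for i in assignment.labels], name="cluster"
    )
    table = pd.crosstab(clusters, groups.rename("group"))
    return table
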