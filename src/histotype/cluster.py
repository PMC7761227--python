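"""Imaging-subtype discovery by consensus clustering, and its validation.

The discovery engine is partition-around-medoids (PAM) under the Spearman
distance d(i, j) = 1 - rho_s(row_i, row_j). Stability is assessed by
consensus clustering: many replicates each draw a random 80% of the
specimens and 80% of the features, recompute the distance on the subset,
re-run PAM, and accumulate how often each co-sampled specimen pair lands
in the same cluster. The number of clusters K is chosen from the area under
the CDF of consensus values: K is the largest value whose relative
delta-area gain still exceeds a threshold. Cross-cohort reproducibility is
quantified by the in-group proportion (IGP): validation specimens are
assigned to the nearest discovery centroid, and IGP(g) is the fraction of
specimens assigned to g whose nearest validation neighbor is also
assigned to g, with a label-permutation null for significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state

__all__ = [
    "spearman_distance",
    "classify_to_centroids",
    "pam",
    "PAM",
    "ConsensusCluster",
    "ConsensusResult",
    "cdf_delta_area",
    "consensus_labels",
    "igp",
    "IGPResult",
    "match_clusters",
]


# ---------------------------------------------------------------------------
# Spearman distance
# ---------------------------------------------------------------------------

def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, X)


def spearman_distance(X, specimen_ids=None) -> np.ndarray:
    """Pairwise 1 - Spearman rank correlation between the rows of X.

    Ranks use midranks for ties. A constant row has no defined rank
    correlation and raises, naming the offending specimen.
    """
    if isinstance(X, pd.DataFrame):
        specimen_ids = X.index.tolist() if specimen_ids is None else specimen_ids
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a 2-D matrix with at least 3 features")
    R = _rank_rows(X)
    sd = R.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.where(sd == 0)[0][0])
        name = specimen_ids[bad] if specimen_ids is not None else bad
        raise ValueError(f"specimen {name!r} has a constant feature row; "
                         "Spearman distance undefined")
    C = np.corrcoef(R)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 2.0)


# ---------------------------------------------------------------------------
# PAM (k-medoids): deterministic BUILD + SWAP
# ---------------------------------------------------------------------------

def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = len(D)
    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    dn = D[first].copy()  # distance to nearest chosen medoid
    while len(medoids) < k:
        chosen = np.zeros(n, dtype=bool)
        chosen[medoids] = True
        # objective if candidate c were added
        obj = np.minimum(dn[None, :], D).sum(axis=1)
        obj[chosen] = np.inf
        c = int(np.argmin(obj))  # argmin takes the lowest index on ties
        medoids.append(c)
        dn = np.minimum(dn, D[c])
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], tol: float = 1e-12) -> list[int]:
    n = len(D)
    medoids = sorted(medoids)
    while True:
        Dm = D[medoids]  # k x n
        order = np.argsort(Dm, axis=0, kind="stable")
        dn = Dm[order[0], np.arange(n)]
        ds = Dm[order[1], np.arange(n)] if len(medoids) > 1 else np.full(n, np.inf)
        nearest = order[0]
        current = dn.sum()

        best = (current - tol, None, None)
        non_medoids = [c for c in range(n) if c not in medoids]
        cand_D = D[non_medoids]  # c x n
        for mi, m in enumerate(medoids):
            base = np.where(nearest == mi, ds, dn)
            objs = np.minimum(base[None, :], cand_D).sum(axis=1)
            ci = int(np.argmin(objs))
            if objs[ci] < best[0]:
                best = (objs[ci], mi, non_medoids[ci])
        if best[1] is None:
            return medoids
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)


def pam(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """PAM clustering on a precomputed distance matrix.

    Returns (labels in 0..k-1 ordered by medoid index, medoid indices).
    Ties in the nearest-medoid assignment go to the lowest cluster index.
    """
    D = np.asarray(D, dtype=float)
    n = len(D)
    if not (0 < k < n):
        raise ValueError(f"k must be in (0, n); got k={k}, n={n}")
    medoids = _pam_swap(D, _pam_build(D, k))
    labels = np.argmin(D[medoids], axis=0)
    return labels, np.asarray(medoids)


def pam_objective(D: np.ndarray, medoids) -> float:
    return float(D[list(medoids)].min(axis=0).sum())


class PAM(BaseEstimator, ClusterMixin):
    """Partition-around-medoids estimator.

    Parameters
    ----------
    n_clusters : int
    metric : {"precomputed", "euclidean", "spearman"}
        With "precomputed", ``fit(X)`` expects a square distance matrix.

    Attributes
    ----------
    labels_ : cluster assignment per sample
    medoid_indices_ : row indices of the medoids
    inertia_ : total distance of samples to their nearest medoid
    """

    def __init__(self, n_clusters: int = 3, metric: str = "spearman"):
        self.n_clusters = n_clusters
        self.metric = metric

    def _distances(self, X) -> np.ndarray:
        if self.metric == "precomputed":
            D = np.asarray(X, dtype=float)
            if D.ndim != 2 or D.shape[0] != D.shape[1]:
                raise ValueError("precomputed metric expects a square matrix")
            return D
        if self.metric == "spearman":
            return spearman_distance(X)
        if self.metric == "euclidean":
            A = np.asarray(X, dtype=float)
            return np.sqrt(((A[:, None, :] - A[None, :, :]) ** 2).sum(-1))
        raise ValueError(f"unknown metric {self.metric!r}")

    def fit(self, X, y=None):
        D = self._distances(X)
        self.labels_, self.medoid_indices_ = pam(D, self.n_clusters)
        self.inertia_ = pam_objective(D, self.medoid_indices_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Everything the consensus run produced, per candidate K."""

    k_range: list[int]
    consensus: dict[int, np.ndarray]
    cdf_areas: dict[int, float]
    delta_areas: dict[int, float]
    optimal_k: int
    labels: np.ndarray  # final labels (1..K) at optimal K
    labels_per_k: dict[int, np.ndarray]
    specimen_ids: list | None = None
    params: dict = field(default_factory=dict)


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangle consensus values
    over [0, 1]; equals 1 - mean(values)."""
    v = consensus[np.triu_indices_from(consensus, k=1)]
    return float(1.0 - v.mean())


def cdf_delta_area(
    consensus_by_k: dict[int, np.ndarray], delta_min: float = 0.1
) -> tuple[int, dict[int, float], dict[int, float]]:
    """Select K from consensus matrices by the relative delta-area rule.

    delta(K_min) = A(K_min); delta(K) = (A(K) - A(K-1)) / A(K-1) for larger
    K. The optimal K is the largest K whose delta exceeds ``delta_min``.
    """
    ks = sorted(consensus_by_k)
    if len(ks) < 3:
        raise ValueError("need at least 3 candidate K values")
    areas = {k: _cdf_area(consensus_by_k[k]) for k in ks}
    deltas: dict[int, float] = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        deltas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
    above = [k for k in ks if deltas[k] > delta_min]
    optimal = max(above) if above else ks[0]
    return optimal, areas, deltas


def consensus_labels(consensus: np.ndarray, k: int) -> np.ndarray:
    """Final labels (1..k) by average-linkage hierarchical clustering on
    1 - consensus."""
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    Z = linkage(squareform(d, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


class ConsensusCluster(BaseEstimator, ClusterMixin):
    """Consensus clustering with PAM on resampled Spearman distances.

    Each of ``n_resamples`` replicates draws ``ceil(item_fraction * n)``
    specimens and ``ceil(feature_fraction * p)`` features, both without
    replacement, recomputes the Spearman distance on the subset, and runs
    PAM at every K in ``k_range``. The consensus value of a specimen pair
    is its co-clustering count divided by its co-sampling count (the
    convention of the consensus-clustering method this follows); pairs
    never co-sampled get 0.

    Attributes (after ``fit``)
    --------------------------
    consensus_ : dict K -> (n, n) consensus matrix
    cdf_areas_, delta_areas_ : dict K -> float
    optimal_k_ : selected number of clusters
    labels_ : final labels (1..K) at ``optimal_k_``
    labels_per_k_ : dict K -> labels from the consensus matrix at that K
    """

    def __init__(
        self,
        k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
        n_resamples: int = 10_000,
        feature_fraction: float = 0.8,
        item_fraction: float = 0.8,
        delta_min: float = 0.1,
        random_state: int | None = None,
    ):
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.feature_fraction = feature_fraction
        self.item_fraction = item_fraction
        self.delta_min = delta_min
        self.random_state = random_state

    def fit(self, X, y=None):
        ids = X.index.tolist() if isinstance(X, pd.DataFrame) else None
        A = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        n, p = A.shape
        ks = sorted(int(k) for k in self.k_range)
        if not (0 < self.feature_fraction <= 1):
            raise ValueError("feature_fraction must be in (0, 1]")
        if not (0 < self.item_fraction <= 1):
            raise ValueError("item_fraction must be in (0, 1]")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if n < 2 * max(ks):
            raise ValueError(f"need n >= 2*K_max specimens (n={n}, K_max={max(ks)})")
        rng = check_random_state(self.random_state)
        n_feat = int(np.ceil(self.feature_fraction * p))
        n_item = int(np.ceil(self.item_fraction * n))
        if n_item <= max(ks):
            raise ValueError("item subsample smaller than K_max")

        acc = {k: np.zeros((n, n)) for k in ks}
        copresent = np.zeros((n, n))
        for _ in range(self.n_resamples):
            items = np.sort(rng.choice(n, size=n_item, replace=False))
            feats = rng.choice(p, size=n_feat, replace=False)
            D = spearman_distance(A[np.ix_(items, feats)])
            ij = np.ix_(items, items)
            copresent[ij] += 1
            for k in ks:
                labels, _ = pam(D, k)
                acc[k][ij] += labels[:, None] == labels[None, :]

        with np.errstate(invalid="ignore", divide="ignore"):
            self.consensus_ = {
                k: np.where(copresent > 0, acc[k] / np.maximum(copresent, 1), 0.0)
                for k in ks
            }
        for M in self.consensus_.values():
            np.fill_diagonal(M, 1.0)
        self.copresence_ = copresent
        self.optimal_k_, self.cdf_areas_, self.delta_areas_ = cdf_delta_area(
            self.consensus_, self.delta_min
        )
        self.labels_per_k_ = {k: consensus_labels(self.consensus_[k], k) for k in ks}
        self.labels_ = self.labels_per_k_[self.optimal_k_]
        self.specimen_ids_ = ids
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def result_(self) -> ConsensusResult:
        return ConsensusResult(
            k_range=sorted(int(k) for k in self.k_range),
            consensus=self.consensus_,
            cdf_areas=self.cdf_areas_,
            delta_areas=self.delta_areas_,
            optimal_k=self.optimal_k_,
            labels=self.labels_,
            labels_per_k=self.labels_per_k_,
            specimen_ids=self.specimen_ids_,
            params={
                "n_resamples": self.n_resamples,
                "feature_fraction": self.feature_fraction,
                "item_fraction": self.item_fraction,
                "delta_min": self.delta_min,
                "random_state": self.random_state,
            },
        )


def consensus_cluster(
    X,
    k_range=(2, 3, 4, 5, 6),
    n_resamples: int = 10_000,
    feature_fraction: float = 0.8,
    item_fraction: float = 0.8,
    delta_min: float = 0.1,
    seed: int | None = None,
) -> ConsensusResult:
    """Functional wrapper over :class:`ConsensusCluster`."""
    est = ConsensusCluster(
        k_range=tuple(k_range),
        n_resamples=n_resamples,
        feature_fraction=feature_fraction,
        item_fraction=item_fraction,
        delta_min=delta_min,
        random_state=seed,
    ).fit(X)
    return est.result_()


# ---------------------------------------------------------------------------
# in-group proportion
# ---------------------------------------------------------------------------

def _spearman_dist_to(rows: np.ndarray, others: np.ndarray) -> np.ndarray:
    """1 - Spearman correlation between each row of ``rows`` and each row
    of ``others`` (rows x others)."""
    Ra = _rank_rows(rows)
    Rb = _rank_rows(others)
    Ra = (Ra - Ra.mean(1, keepdims=True)) / Ra.std(1, keepdims=True)
    Rb = (Rb - Rb.mean(1, keepdims=True)) / Rb.std(1, keepdims=True)
    return 1.0 - (Ra @ Rb.T) / Ra.shape[1]


def classify_to_centroids(X_disc, labels_disc, X_val) -> np.ndarray:
    """Assign each validation specimen to the nearest discovery-cluster
    centroid (feature-wise mean) under 1 - Spearman."""
    Xd = np.asarray(
        X_disc.to_numpy(dtype=float) if isinstance(X_disc, pd.DataFrame) else X_disc,
        dtype=float,
    )
    Xv = np.asarray(
        X_val.to_numpy(dtype=float) if isinstance(X_val, pd.DataFrame) else X_val,
        dtype=float,
    )
    labels_disc = np.asarray(labels_disc)
    groups = np.unique(labels_disc)
    centroids = np.vstack([Xd[labels_disc == g].mean(axis=0) for g in groups])
    return groups[np.argmin(_spearman_dist_to(Xv, centroids), axis=1)]


@dataclass
class IGPResult:
    igp: dict[int, float]
    p_values: dict[int, float]
    val_labels: np.ndarray
    centroid_map: dict[int, int] = field(default_factory=dict)


def igp(
    X_disc,
    labels_disc,
    X_val,
    n_permutations: int = 1000,
    random_state: int | None = None,
) -> IGPResult:
    """In-group proportion of discovery clusters in a validation cohort.

    Validation specimens are classified to the nearest discovery-cluster
    centroid (feature-wise mean) under 1 - Spearman; IGP(g) is the
    proportion of specimens classified to g whose nearest validation
    neighbor (same distance) is also classified to g. Significance comes
    from permuting the classified validation labels.
    """
    Xd = np.asarray(
        X_disc.to_numpy(dtype=float) if isinstance(X_disc, pd.DataFrame) else X_disc,
        dtype=float,
    )
    Xv = np.asarray(
        X_val.to_numpy(dtype=float) if isinstance(X_val, pd.DataFrame) else X_val,
        dtype=float,
    )
    labels_disc = np.asarray(labels_disc)
    groups = np.unique(labels_disc)
    for g in groups:
        if (labels_disc == g).sum() < 2:
            raise ValueError(f"discovery cluster {g} has fewer than 2 members")

    val_labels = classify_to_centroids(Xd, labels_disc, Xv)

    Dv = _spearman_dist_to(Xv, Xv)
    np.fill_diagonal(Dv, np.inf)
    nn = np.argmin(Dv, axis=1)
    nn_labels = val_labels[nn]

    def _igp(assigned: np.ndarray) -> dict[int, float]:
        out = {}
        for g in groups:
            members = assigned == g
            out[int(g)] = (
                float((assigned[nn[members]] == g).mean()) if members.any() else np.nan
            )
        return out

    observed = _igp(val_labels)
    rng = check_random_state(random_state)
    exceed = {int(g): 0 for g in groups}
    for _ in range(n_permutations):
        perm = rng.permutation(val_labels)
        perm_members = {g: perm == g for g in groups}
        for g in groups:
            members = perm_members[g]
            val = float((perm[nn[members]] == g).mean()) if members.any() else np.nan
            if val == val and observed[int(g)] == observed[int(g)] and val >= observed[int(g)]:
                exceed[int(g)] += 1
    p_values = {
        g: (exceed[g] + 1) / (n_permutations + 1) for g in exceed
    }
    return IGPResult(igp=observed, p_values=p_values, val_labels=val_labels)


def match_clusters(
    X_disc, labels_disc, X_val, labels_val
) -> dict[int, int]:
    """Match validation clusters to discovery clusters by maximal centroid
    Spearman correlation (optimal one-to-one assignment)."""
    Xd = np.asarray(X_disc, dtype=float) if not isinstance(X_disc, pd.DataFrame) else X_disc.to_numpy(float)
    Xv = np.asarray(X_val, dtype=float) if not isinstance(X_val, pd.DataFrame) else X_val.to_numpy(float)
    gd = np.unique(labels_disc)
    gv = np.unique(labels_val)
    cd = np.vstack([Xd[np.asarray(labels_disc) == g].mean(axis=0) for g in gd])
    cv = np.vstack([Xv[np.asarray(labels_val) == g].mean(axis=0) for g in gv])
    cost = _spearman_dist_to(cv, cd)  # low distance = good match
    ri, ci = linear_sum_assignment(cost)
    return {int(gv[r]): int(gd[c]) for r, c in zip(ri, ci)}
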