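"""Fuzzy c-means classification of area-response behaviours.

Area-response windows are normalized by their own standard deviation (so the
clustering sees shape, not magnitude) and grouped by fuzzy c-means (FCM) with
Euclidean distance. With k = 3 the clusters are mapped to the three canonical
behaviours: *ratcheted* (stabilized constriction), *unratcheted* (constriction
followed by re-expansion) and *unconstricting* (no measurable area change).

FCM is implemented directly (standard Bezdek updates, fuzzifier m = 2,
random initial memberships): membership of datum i in cluster j is
proportional to d_ij^(-2/(m-1)) and centroids are membership^m-weighted
means, iterated until the membership matrix stops changing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .datatypes import ValidationError

SEMANTIC_ORDER = ("ratcheted", "unratcheted", "unconstricting")


def normalize_responses(
    matrix: np.ndarray, sd_floor: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Divide each response row by its own sample s.d.

    Returns (normalized rows, kept row indices, excluded row indices).
    Rows with s.d. below ``sd_floor`` (degenerate, e.g. all-zero) or with
    missing values are excluded and reported.
    """
    matrix = np.asarray(matrix, dtype=float)
    finite = ~np.isnan(matrix).any(axis=1)
    sd = np.full(len(matrix), 0.0)
    sd[finite] = np.std(matrix[finite], axis=1, ddof=1)
    keep = finite & (sd > sd_floor)
    out = matrix[keep] / sd[keep, None]
    return out, np.where(keep)[0], np.where(~keep)[0]


def _fcm_once(data, k, m, tol, max_iter, rng):
    n = len(data)
    u = rng.random((n, k))
    u /= u.sum(axis=1, keepdims=True)
    objective_path = []
    converged = False
    for _ in range(max_iter):
        um = u**m
        centroids = (um.T @ data) / um.sum(axis=0)[:, None]
        d2 = ((data[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        objective_path.append(float((um * d2).sum()))
        zero = d2 <= 1e-300
        u_new = np.zeros_like(u)
        any_zero = zero.any(axis=1)
        if any_zero.any():
            # datum coincides with a centroid: full membership there
            rows = np.where(any_zero)[0]
            u_new[rows, np.argmax(zero[rows], axis=1)] = 1.0
        rest = ~any_zero
        if rest.any():
            inv = d2[rest] ** (-1.0 / (m - 1.0))
            u_new[rest] = inv / inv.sum(axis=1, keepdims=True)
        delta = np.max(np.abs(u_new - u))
        u = u_new
        if delta < tol:
            converged = True
            break
    um = u**m
    centroids = (um.T @ data) / um.sum(axis=0)[:, None]
    return centroids, u, objective_path, converged


@dataclass
class BehaviourClassModel:
    k: int
    centroids: np.ndarray
    m: float
    memberships: np.ndarray
    assignments: np.ndarray
    seed: int | None
    converged: bool
    objective_path: list[float] = field(default_factory=list)
    semantic_labels: dict[int, str] = field(default_factory=dict)
    kept_rows: np.ndarray | None = None
    excluded_rows: np.ndarray | None = None

    def labels(self) -> np.ndarray:
        """Semantic label per categorized row (cluster_i if unlabelled)."""
        name = lambda j: self.semantic_labels.get(j, f"cluster_{j}")
        return np.array([name(j) for j in self.assignments])


def fcm_cluster(
    data: np.ndarray,
    k: int = 3,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | None = None,
    n_init: int = 1,
) -> BehaviourClassModel:
    """Fuzzy c-means on normalized response rows.

    Rows containing NaN are excluded up front (they remain uncategorized);
    memberships of each kept row sum to 1 and assignments are the argmax
    memberships. Deterministic for a fixed seed. ``n_init`` > 1 restarts
    from independent random memberships and keeps the solution with the
    lowest objective (the data form a behavioural continuum, so single
    starts can settle in secondary optima).
    """
    data = np.asarray(data, dtype=float)
    keep = ~np.isnan(data).any(axis=1)
    x = data[keep]
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(x):
        raise ValidationError(f"k={k} exceeds the {len(x)} complete rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        result = _fcm_once(x, k, m, tol, max_iter, rng)
        if best is None or result[2][-1] < best[2][-1]:
            best = result
    centroids, u, path, converged = best
    return BehaviourClassModel(
        k=k,
        centroids=centroids,
        m=m,
        memberships=u,
        assignments=np.argmax(u, axis=1),
        seed=seed,
        converged=converged,
        objective_path=path,
        kept_rows=np.where(keep)[0],
        excluded_rows=np.where(~keep)[0],
    )


def rand_index(labels_a, labels_b) -> float:
    """Plain Rand index: fraction of unordered pairs on which two labelings
    agree (both together or both apart). Invariant to label renaming."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValidationError("labelings differ in length")
    n = len(a)
    if n < 2:
        raise ValidationError("need at least two items")
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    agree = same_a == same_b
    iu = np.triu_indices(n, k=1)
    return float(agree[iu].mean())


@dataclass
class ClusterDiagnostics:
    k_values: list[int]
    distortion: dict[int, float]
    silhouette: dict[int, float]
    pca_variance_fractions: np.ndarray
    rand_indices: dict[int, list[float]]

    def mean_rand(self, k: int) -> float:
        return float(np.mean(self.rand_indices[k]))


def diagnostics(
    data: np.ndarray,
    k_range=(2, 3, 4, 5, 6),
    n_replicates: int = 20,
    seed: int | None = None,
) -> ClusterDiagnostics:
    """Cluster-count diagnostics on a normalized response matrix.

    Per k: average distortion (mean member-to-centroid distance), mean
    silhouette, and pairwise Rand indices across seeded FCM replicates.
    Also reports the PCA variance-explained fractions of the matrix. These
    diagnostics report; they never gate the choice of k.
    """
    data = np.asarray(data, dtype=float)
    data = data[~np.isnan(data).any(axis=1)]
    rng = np.random.default_rng(seed)
    pca = PCA().fit(data)

    distortion, silhouette, rand = {}, {}, {}
    for k in k_range:
        models = [
            fcm_cluster(data, k=k, seed=int(rng.integers(2**31)))
            for _ in range(n_replicates)
        ]
        best = models[0]
        dists = np.linalg.norm(data - best.centroids[best.assignments], axis=1)
        distortion[k] = float(dists.mean())
        labels = best.assignments
        silhouette[k] = (
            float(silhouette_score(data, labels)) if len(set(labels)) > 1 else float("nan")
        )
        rand[k] = [
            rand_index(m1.assignments, m2.assignments)
            for m1, m2 in combinations(models, 2)
        ]
    return ClusterDiagnostics(
        k_values=list(k_range),
        distortion=distortion,
        silhouette=silhouette,
        pca_variance_fractions=pca.explained_variance_ratio_,
        rand_indices=rand,
    )


def label_classes(
    model: BehaviourClassModel,
    flat_tol: float = 0.8,
    recovery_frac: float = 0.25,
) -> dict[int, str]:
    """Map k = 3 centroids to semantic behaviour names.

    Per centroid (in normalized units): depth d = -min(centroid), recovery
    r = centroid[end] - min(centroid). d < flat_tol -> unconstricting (no
    coherent constriction: per-row unit-s.d. normalization means a real class
    signal pushes the centroid well below -1, while a noise/weak cluster's
    centroid hovers near 0); else r >= recovery_frac * d -> unratcheted
    (constriction relaxes); else ratcheted (constriction is stabilized).
    The recovery fraction tolerates the tissue-contraction drift that
    continues through the tail of every window.
    Centroids are visited in order of increasing depth so the flattest one
    claims `unconstricting` first. Other k get generic cluster_i names.
    """
    if model.k != 3:
        model.semantic_labels = {j: f"cluster_{j}" for j in range(model.k)}
        return model.semantic_labels
    depth = -model.centroids.min(axis=1)
    recovery = model.centroids[:, -1] - model.centroids.min(axis=1)
    labels: dict[int, str] = {}
    for j in np.argsort(depth):
        if depth[j] < flat_tol:
            labels[j] = "unconstricting"
        elif recovery[j] >= recovery_frac * depth[j]:
            labels[j] = "unratcheted"
        else:
            labels[j] = "ratcheted"
    if len(set(labels.values())) != 3:
        raise ValidationError(
            "two centroids map to the same behaviour label; adjust flat_tol / "
            f"recovery_frac (got {labels})"
        )
    model.semantic_labels = labels
    return labels


def classify_windows(
    matrix: np.ndarray,
    k: int = 3,
    seed: int | None = None,
    flat_tol: float = 0.8,
    recovery_frac: float = 0.25,
    n_init: int = 8,
    **fcm_kwargs,
) -> tuple[BehaviourClassModel, np.ndarray]:
    """Normalize rows, cluster, and semantically label: the full pipeline step.

    Returns the fitted model and a per-input-row label array in which rows
    excluded by normalization are 'uncategorized'.
    """
    normed, kept, excluded = normalize_responses(np.asarray(matrix, float))
    model = fcm_cluster(normed, k=k, seed=seed, n_init=n_init, **fcm_kwargs)
    label_classes(model, flat_tol=flat_tol, recovery_frac=recovery_frac)
    labels = np.array(["uncategorized"] * len(matrix), dtype=object)
    labels[kept] = model.labels()
    model.kept_rows = kept
    model.excluded_rows = excluded
    return model, labels
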