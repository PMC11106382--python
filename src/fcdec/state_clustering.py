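"""K-means state decomposition of windowed EC matrices.

Windows from all subjects are pooled, each EC matrix vectorized over its
off-diagonal entries, and clustered with a hybrid k-means: points are
assigned to the nearest centroid under the Manhattan (L1) distance while
centroids are updated as cluster means.  The number of states is selected
by the silhouette coefficient (L1) with the Calinski-Harabasz index as the
tie-breaker.  States are summarized by centroid matrices and per-group
occupancy fractions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .granger_dec import ECMatrix
from .io_config import CohortManifest

__all__ = [
    "StateModel",
    "manhattan_distance",
    "vectorize_ec",
    "unvectorize_ec",
    "kmeans_l1",
    "select_k",
    "occupancy",
    "state_centroid_matrices",
]


@dataclasses.dataclass
class StateModel:
    """Fitted state decomposition over pooled (subject, window) points."""

    k: int
    centroids: np.ndarray          # (k, d) in vectorized-EC space
    assignments: np.ndarray        # state label in 1..k per pooled window
    point_ids: list[tuple[str, int]]  # (subject_id, window_index) per pooled window
    objective: float               # final within-cluster summed squared error E
    objective_trace: np.ndarray    # E after each iteration of the winning restart
    selection_curves: dict | None = None  # k -> {"silhouette": ..., "calinski_harabasz": ...}


def manhattan_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Sum of elementwise absolute differences."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors have different lengths")
    return float(np.abs(u - v).sum())


def _offdiag_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major ordered-pair (i, j), i != j, indexing for vectorization."""
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mask = ii != jj
    return ii[mask], jj[mask]


def vectorize_ec(mat: np.ndarray) -> np.ndarray:
    """All off-diagonal entries in fixed row-major ordered-pair order."""
    n = mat.shape[0]
    i, j = _offdiag_index(n)
    return np.asarray(mat, dtype=float)[i, j]


def unvectorize_ec(vec: np.ndarray, n: int) -> np.ndarray:
    mat = np.zeros((n, n))
    i, j = _offdiag_index(n)
    mat[i, j] = vec
    return mat


def _sq_objective(points: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    diff = points - centroids[labels]
    return float(np.einsum("ij,ij->", diff, diff))


def _kmeans_once(
    points: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    n = points.shape[0]
    centroids = points[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    trace = []
    for _ in range(max_iter):
        d = cdist(points, centroids, metric="cityblock")
        new_labels = np.argmin(d, axis=1)
        # empty cluster: re-seed at the point farthest (L1) from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(d[np.arange(n), new_labels]))
                centroids[c] = points[far]
                new_labels[far] = c
        for c in range(k):
            centroids[c] = points[new_labels == c].mean(axis=0)
        trace.append(_sq_objective(points, centroids, new_labels))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return centroids, labels, trace[-1], np.asarray(trace)


def kmeans_l1(
    points: np.ndarray, k: int, seed: int = 0, n_restarts: int = 50, max_iter: int = 300
) -> StateModel:
    """L1-assignment / mean-update k-means, best of ``n_restarts`` by squared error E."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < k:
        raise ValueError("need at least k points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        cen, lab, obj, trace = _kmeans_once(points, k, rng, max_iter)
        if best is None or obj < best[2]:
            best = (cen, lab, obj, trace)
    cen, lab, obj, trace = best
    return StateModel(
        k=k,
        centroids=cen,
        assignments=lab + 1,
        point_ids=[("", i) for i in range(points.shape[0])],
        objective=obj,
        objective_trace=trace,
    )


def select_k(
    points: np.ndarray,
    k_range=range(2, 11),
    seed: int = 0,
    n_restarts: int = 50,
    silhouette_sample: int = 2000,
) -> tuple[int, dict]:
    """Pick k by silhouette (L1), ties broken by Calinski-Harabasz, then smaller k.

    For large pooled-window sets the silhouette is evaluated on a seeded
    subsample (default 2000 points) to keep the pairwise-distance cost bounded.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range empty after bounding by the number of points")
    if np.allclose(points, points[0]):
        raise ValueError("all points identical: no cluster structure to select")
    curves: dict[int, dict] = {}
    models: dict[int, StateModel] = {}
    sil_kwargs = {}
    if n > silhouette_sample:
        sil_kwargs = {"sample_size": silhouette_sample, "random_state": seed & 0x7FFFFFFF}
    for k in ks:
        model = kmeans_l1(points, k, seed=seed + k, n_restarts=n_restarts)
        labels = model.assignments
        if len(np.unique(labels)) < 2:
            sil, ch = -1.0, 0.0
        else:
            sil = float(silhouette_score(points, labels, metric="manhattan", **sil_kwargs))
            ch = float(calinski_harabasz_score(points, labels))
        curves[k] = {"silhouette": sil, "calinski_harabasz": ch}
        models[k] = model
    k_best = min(
        ks,
        key=lambda k: (-round(curves[k]["silhouette"], 12), -curves[k]["calinski_harabasz"], k),
    )
    return k_best, curves


def fit_states(
    ec_lists: dict[str, list[ECMatrix]],
    k: int | None = None,
    k_range=range(2, 11),
    seed: int = 0,
    n_restarts: int = 50,
) -> StateModel:
    """Pool all subjects' windowed EC matrices and fit the state model.

    If ``k`` is None it is selected from the data via :func:`select_k`.
    """
    point_ids = []
    rows = []
    for sid in sorted(ec_lists):
        for ec in ec_lists[sid]:
            rows.append(vectorize_ec(ec.values))
            point_ids.append((sid, ec.window_index))
    points = np.asarray(rows)
    curves = None
    if k is None:
        k, curves = select_k(points, k_range=k_range, seed=seed, n_restarts=n_restarts)
    model = kmeans_l1(points, k, seed=seed + k, n_restarts=n_restarts)
    model.point_ids = point_ids
    model.selection_curves = curves
    return model


def occupancy(model: StateModel, manifest: CohortManifest | None = None) -> dict:
    """Fraction of windows per state, overall and per group; counts alongside."""
    labels = model.assignments
    total = labels.shape[0]
    out: dict = {"overall": {}, "by_group": {}}
    for s in range(1, model.k + 1):
        cnt = int(np.sum(labels == s))
        out["overall"][s] = {"count": cnt, "fraction": cnt / total}
    if manifest is not None:
        groups = {sid: manifest.group_of(sid) for sid in {pid for pid, _ in model.point_ids}}
        for g in ("patient", "control"):
            mask = np.array([groups[pid] == g for pid, _ in model.point_ids])
            tot_g = int(mask.sum())
            if tot_g == 0:
                continue
            out["by_group"][g] = {
                s: {
                    "count": int(np.sum(labels[mask] == s)),
                    "fraction": float(np.sum(labels[mask] == s) / tot_g),
                }
                for s in range(1, model.k + 1)
            }
    return out


def state_centroid_matrices(model: StateModel, n_rois: int) -> list[np.ndarray]:
    """Centroids reshaped back to directed n x n matrices (zero diagonal)."""
    return [unvectorize_ec(c, n_rois) for c in model.centroids]
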