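"""Static functional-connectivity networks.

Per subject: the N x N Pearson correlation matrix over ROI time series, its
Fisher r-to-z transform, and the family of binarized networks obtained by
keeping the strongest edges at each sparsity on a fixed grid.  The grid is
then restricted to sparsities where every subject's network has mean degree
above 2*log(N) and small-world sigma above 1.1.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Mapping, Sequence

import numpy as np

from .io_config import SubjectTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "FCMatrix",
    "ZMatrix",
    "BinaryNetwork",
    "AdmissibleRange",
    "pearson_fc",
    "fisher_z",
    "threshold_by_sparsity",
    "edge_count_for_sparsity",
    "admissible_sparsity_range",
]


@dataclasses.dataclass
class FCMatrix:
    """Symmetric N x N Pearson correlation matrix, unit diagonal."""

    values: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        self.values = v


@dataclasses.dataclass
class ZMatrix:
    """Fisher r-to-z transformed FC matrix; the diagonal takes no part in edge selection."""

    values: np.ndarray
    subject_id: str


@dataclasses.dataclass
class BinaryNetwork:
    """Undirected 0/1 adjacency at a given sparsity; no self-loops."""

    adjacency: np.ndarray
    sparsity: float
    subject_id: str

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with a zero diagonal")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def pearson_fc(ts: SubjectTimeSeries) -> FCMatrix:
    """Pearson correlation between all ROI pairs of one subject."""
    X = ts.data
    if X.shape[0] < 3:
        raise ValueError("need at least 3 time points for a correlation matrix")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"constant time series in ROI column {bad + 1} (1-based)")
    r = np.corrcoef(X, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return FCMatrix(values=r, subject_id=ts.subject_id)


def fisher_z(fc: FCMatrix, clip: float = 1.0 - 1e-7) -> ZMatrix:
    """Elementwise arctanh of the off-diagonal; |r| at 1 is clipped first.

    arctanh is strictly increasing, so edge ranking is unchanged.
    """
    r = fc.values.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    n_clip = int(np.sum(np.abs(r[off]) >= 1.0))
    if n_clip:
        logger.info("fisher_z: clipped %d off-diagonal |r| >= 1 to %.7g", n_clip, clip)
    r[off] = np.clip(r[off], -clip, clip)
    z = np.arctanh(r * off)  # diagonal mapped to 0, excluded downstream anyway
    return ZMatrix(values=z, subject_id=fc.subject_id)


def edge_count_for_sparsity(sparsity: float, n_nodes: int) -> int:
    """round-half-up of sparsity * N(N-1)/2."""
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(sparsity * n_pairs + 0.5))


def _ranked_pairs(values: np.ndarray, rank_by: str) -> np.ndarray:
    """Upper-triangle pairs ordered strongest first.

    Ordering key: larger value first (signed by default, absolute optionally),
    ties broken by smaller row index then smaller column index.
    """
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    if rank_by == "abs":
        w = np.abs(w)
    elif rank_by != "signed":
        raise ValueError(f"rank_by must be 'signed' or 'abs', got {rank_by!r}")
    order = np.lexsort((ju, iu, -w))
    return np.column_stack((iu[order], ju[order]))


def threshold_by_sparsity(
    z: ZMatrix, sparsity: float, rank_by: str = "signed"
) -> BinaryNetwork:
    """Keep the ``round(sparsity * N(N-1)/2)`` strongest off-diagonal entries as edges."""
    if not (0 < sparsity < 1):
        raise ValueError(f"sparsity must lie in (0, 1), got {sparsity}")
    n = z.values.shape[0]
    m = edge_count_for_sparsity(sparsity, n)
    if m == 0:
        raise ValueError(f"sparsity {sparsity} retains zero edges on {n} nodes")
    pairs = _ranked_pairs(z.values, rank_by)[:m]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[pairs[:, 0], pairs[:, 1]] = 1
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, sparsity=float(sparsity), subject_id=z.subject_id)


@dataclasses.dataclass
class AdmissibleRange:
    """Sub-grid of sparsities passing both admissibility criteria, with failure log."""

    s_min: float
    s_max: float
    grid: np.ndarray  # the passing sparsities, ascending
    failures: list[str]


def admissible_sparsity_range(
    networks: Mapping[float, Sequence[BinaryNetwork]],
    sigma_fn: Callable[[BinaryNetwork], float],
    log_base: float | None = None,
    sigma_threshold: float = 1.1,
) -> AdmissibleRange:
    """Restrict the grid to sparsities where every subject passes both criteria.

    Criterion 1: mean degree > 2*log(N) (natural log by default, configurable).
    Criterion 2: small-world sigma (from ``sigma_fn``) > ``sigma_threshold``
    for every subject's network.
    """
    if not networks:
        raise ValueError("empty candidate sparsity grid")
    failures: list[str] = []
    passing: list[float] = []
    for s in sorted(networks):
        nets = networks[s]
        ok = True
        for net in nets:
            n = net.n_nodes
            bound = 2.0 * (math.log(n) if log_base is None else math.log(n, log_base))
            mean_deg = 2.0 * net.n_edges / n
            if not mean_deg > bound:
                failures.append(
                    f"s={s:g}: subject {net.subject_id} mean degree {mean_deg:.3f} <= 2log(N)={bound:.3f}"
                )
                ok = False
                break
            sigma = sigma_fn(net)
            if not sigma > sigma_threshold:
                failures.append(
                    f"s={s:g}: subject {net.subject_id} sigma {sigma:.3f} <= {sigma_threshold}"
                )
                ok = False
                break
        if ok:
            passing.append(float(s))
    for msg in failures:
        logger.info("admissible_sparsity_range: %s", msg)
    if not passing:
        raise ValueError(
            "no admissible sparsity: every grid point failed a criterion; "
            "widen or shift the sparsity grid"
        )
    return AdmissibleRange(
        s_min=min(passing), s_max=max(passing), grid=np.asarray(passing), failures=failures
    )
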