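"""Sliding-window pairwise Granger causality (dynamic effective connectivity).

For each ordered ROI pair (x, y) inside each window, the joint autoregressive
model

    y_t = sum_k A_k x_{t-k} + sum_k B_k y_{t-k} + C z_t + e_t
    x_t = sum_k A'_k y_{t-k} + sum_k B'_k x_{t-k} + C' z_t + e'_t

is estimated by ordinary least squares with an intercept.  The signed path
coefficient sum_k A_k (just A_1 at the default order p = 1) is the directed
influence x -> y; one n x n effective-connectivity (EC) matrix per window is
assembled from these.  The model is fit pairwise per ordered pair, not as a
joint multivariate VAR.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_config import SubjectTimeSeries

__all__ = [
    "WindowSpec",
    "VarFitResult",
    "ECMatrix",
    "make_windows",
    "fit_pair_gc",
    "window_ec_matrix",
    "dec_series",
]


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: 22 TR windows advanced 1 TR at a time by default."""

    length_tr: int = 22
    step_tr: int = 1

    def __post_init__(self) -> None:
        if self.length_tr < 3 or self.step_tr < 1:
            raise ValueError("window length must be >= 3 and step >= 1")

    def count(self, T: int) -> int:
        if T < self.length_tr:
            raise ValueError(f"T={T} shorter than window length {self.length_tr}")
        return (T - self.length_tr) // self.step_tr + 1


@dataclasses.dataclass
class VarFitResult:
    """Both directions of one pairwise joint-AR fit."""

    a: np.ndarray        # A_k, influence x -> y
    b: np.ndarray        # B_k, autoregression of y
    c: np.ndarray        # covariate coefficients (y equation), intercept last
    resid_y: np.ndarray  # E_t
    a_rev: np.ndarray    # A'_k, influence y -> x
    b_rev: np.ndarray    # B'_k, autoregression of x
    c_rev: np.ndarray
    resid_x: np.ndarray  # E'_t
    order: int
    a_se: np.ndarray | None = None      # OLS standard errors of A_k
    a_rev_se: np.ndarray | None = None  # OLS standard errors of A'_k
    flagged: bool = False  # rank-deficient design

    def direction(self) -> int:
        """+1 if x more plausibly drives y than the reverse, else -1.

        Compares the standardized path coefficients (|A|/se), since the two
        equations generally have different residual scales.
        """
        tf = np.abs(self.a / self.a_se).max()
        tr = np.abs(self.a_rev / self.a_rev_se).max()
        return 1 if tf >= tr else -1


@dataclasses.dataclass
class ECMatrix:
    """One window's directed signed EC matrix over the ROI subset.

    Entry (i, j) is the signed influence i -> j; the diagonal is zero and the
    matrix is generally asymmetric.
    """

    values: np.ndarray
    window_index: int
    subject_id: str
    flagged_pairs: list[tuple[int, int]] = dataclasses.field(default_factory=list)


def make_windows(
    ts: SubjectTimeSeries, spec: WindowSpec, roi_subset: tuple[int, ...]
) -> list[np.ndarray]:
    """Ordered list of (length x n_subset) window views over 1-based atlas indices."""
    if not roi_subset:
        raise ValueError("roi_subset is empty")
    if max(roi_subset) > ts.n_rois or min(roi_subset) < 1:
        raise ValueError("roi_subset index outside the atlas")
    n_win = spec.count(ts.n_timepoints)
    cols = np.asarray(roi_subset, dtype=int) - 1
    return [
        ts.data[w * spec.step_tr : w * spec.step_tr + spec.length_tr, cols]
        for w in range(n_win)
    ]


def _lagged_design(
    driver: np.ndarray, target: np.ndarray, p: int, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix [driver lags 1..p | target lags 1..p | covariates | 1] and response."""
    T = target.shape[0]
    rows = T - p
    cols = [np.column_stack([driver[p - k : T - k] for k in range(1, p + 1)]),
            np.column_stack([target[p - k : T - k] for k in range(1, p + 1)])]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov[p:])
    cols.append(np.ones((rows, 1)))
    return np.hstack(cols), target[p:]


def fit_pair_gc(
    x: np.ndarray,
    y: np.ndarray,
    p: int = 1,
    covariates: np.ndarray | None = None,
) -> VarFitResult:
    """OLS fit of the pairwise joint-AR model in both directions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_cov = 0 if covariates is None else (1 if np.ndim(covariates) == 1 else np.shape(covariates)[1])
    if x.shape[0] < 2 * p + n_cov + 3:
        raise ValueError("window too short for the requested model order")

    def _one(driver, target):
        X, yv = _lagged_design(driver, target, p, covariates)
        rank = np.linalg.matrix_rank(X)
        flagged = rank < X.shape[1]
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        if flagged:
            se = np.full(X.shape[1], np.nan)
        else:
            dof = max(X.shape[0] - X.shape[1], 1)
            s2 = float(resid @ resid) / dof
            se = np.sqrt(np.maximum(s2 * np.diag(np.linalg.pinv(X.T @ X)), 1e-300))
        return beta, resid, se, flagged

    beta_y, resid_y, se_y, flag_y = _one(x, y)
    beta_x, resid_x, se_x, flag_x = _one(y, x)
    return VarFitResult(
        a=beta_y[:p],
        b=beta_y[p : 2 * p],
        c=beta_y[2 * p :],
        resid_y=resid_y,
        a_rev=beta_x[:p],
        b_rev=beta_x[p : 2 * p],
        c_rev=beta_x[2 * p :],
        resid_x=resid_x,
        order=p,
        a_se=se_y[:p],
        a_rev_se=se_x[:p],
        flagged=flag_y or flag_x,
    )


def window_ec_matrix(
    window: np.ndarray, p: int = 1, subject_id: str = "", window_index: int = 0
) -> ECMatrix:
    """Directed EC matrix of one window: entry (i, j) = sum_k A_k of the (x=i, y=j) fit.

    Flagged (rank-deficient) pairs are set to 0 and recorded.
    """
    n = window.shape[1]
    values = np.zeros((n, n))
    flagged: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            fit = fit_pair_gc(window[:, i], window[:, j], p=p)
            if fit.flagged:
                flagged.extend([(i, j), (j, i)])
                continue
            values[i, j] = float(fit.a.sum())      # i -> j
            values[j, i] = float(fit.a_rev.sum())  # j -> i
    return ECMatrix(
        values=values, window_index=window_index, subject_id=subject_id, flagged_pairs=flagged
    )


def dec_series(
    ts: SubjectTimeSeries,
    spec: WindowSpec,
    roi_subset: tuple[int, ...],
    p: int = 1,
) -> list[ECMatrix]:
    """One EC matrix per sliding window over the ROI subset."""
    return [
        window_ec_matrix(w, p=p, subject_id=ts.subject_id, window_index=k)
        for k, w in enumerate(make_windows(ts, spec, roi_subset))
    ]
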