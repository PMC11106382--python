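"""Per-state causal-flow measures and covariate-adjusted group inference.

Group comparisons use a linear model ``value ~ group + age + sex`` whose
group-coefficient t-statistic and two-sided p-value are reported; with
constant covariates this reduces exactly to the pooled-variance two-sample
t-test.  Families of p-values are corrected with Benjamini-Hochberg FDR.
Clinical associations use Spearman rank correlation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .io_config import CohortManifest
from .granger_dec import ECMatrix
from .state_clustering import StateModel

logger = logging.getLogger(__name__)

__all__ = [
    "CausalFlow",
    "TestResult",
    "causal_flow",
    "state_mean_ec",
    "adjusted_group_test",
    "fdr_bh",
    "spearman_assoc",
    "nodal_auc_tests",
    "abnormal_node_report",
]


@dataclasses.dataclass
class CausalFlow:
    """In/out-weighted degree per (subject, state, node).

    ``in_weighted[sid][s]`` is the column-sum vector of that subject's mean EC
    matrix over windows assigned to state ``s`` (summed incoming influence);
    ``out_weighted`` holds the row sums.  Subjects with no window in a state
    are absent for that state.
    """

    in_weighted: dict[str, dict[int, np.ndarray]]
    out_weighted: dict[str, dict[int, np.ndarray]]
    n_states: int


@dataclasses.dataclass
class TestResult:
    unit: str
    t: float
    p: float
    p_adjusted: float | None
    mean_patient: float
    mean_control: float

    @property
    def direction(self) -> str:
        return "increased" if self.mean_patient > self.mean_control else "decreased"


def state_mean_ec(
    ec_lists: dict[str, list[ECMatrix]], model: StateModel
) -> dict[str, dict[int, np.ndarray]]:
    """Per subject and state: mean EC matrix over that subject's windows in the state."""
    label_of = dict(zip(model.point_ids, model.assignments))
    out: dict[str, dict[int, np.ndarray]] = {}
    for sid, ecs in ec_lists.items():
        acc: dict[int, list[np.ndarray]] = {}
        for ec in ecs:
            s = int(label_of[(sid, ec.window_index)])
            acc.setdefault(s, []).append(ec.values)
        out[sid] = {s: np.mean(mats, axis=0) for s, mats in acc.items()}
    return out


def causal_flow(ec_lists: dict[str, list[ECMatrix]], model: StateModel) -> CausalFlow:
    """In/out-weighted degree of each node from state-mean EC matrices."""
    means = state_mean_ec(ec_lists, model)
    in_w: dict[str, dict[int, np.ndarray]] = {}
    out_w: dict[str, dict[int, np.ndarray]] = {}
    for sid, per_state in means.items():
        in_w[sid] = {s: m.sum(axis=0) for s, m in per_state.items()}
        out_w[sid] = {s: m.sum(axis=1) for s, m in per_state.items()}
    return CausalFlow(in_weighted=in_w, out_weighted=out_w, n_states=model.k)


def adjusted_group_test(
    values: dict[str, float], manifest: CohortManifest, unit: str = ""
) -> TestResult:
    """Group difference adjusted for age and sex: OLS ``value ~ group + age + sex``."""
    df = manifest.frame.set_index("subject_id").loc[list(values)].copy()
    df["value"] = [values[sid] for sid in df.index]
    df = df.dropna(subset=["value"])
    for g in ("patient", "control"):
        if (df["group"] == g).sum() < 3:
            raise ValueError(f"fewer than 3 non-missing subjects in group {g!r}")
    y = df["value"].to_numpy(dtype=float)
    cols = {"group": (df["group"] == "patient").astype(float).to_numpy()}
    for name, col in (("age", df["age"].to_numpy(dtype=float)),
                      ("sex", (df["sex"] == "M").astype(float).to_numpy())):
        if np.ptp(col) > 0:
            cols[name] = col
        else:
            logger.info("adjusted_group_test(%s): dropping constant covariate %s", unit, name)
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # name the first column whose addition fails to raise the rank
        acc = [X["const"].to_numpy()]
        for name in cols:
            acc.append(X[name].to_numpy())
            if np.linalg.matrix_rank(np.column_stack(acc)) < len(acc):
                raise ValueError(f"singular design: column {name!r} is collinear")
    fit = sm.OLS(y, X).fit()
    return TestResult(
        unit=unit,
        t=float(fit.tvalues["group"]),
        p=float(fit.pvalues["group"]),
        p_adjusted=None,
        mean_patient=float(df.loc[df["group"] == "patient", "value"].mean()),
        mean_control=float(df.loc[df["group"] == "control", "value"].mean()),
    )


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        raise ValueError("need at least 4 paired non-missing observations")
    if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def nodal_auc_tests(
    auc_tables: dict[str, pd.DataFrame], manifest: CohortManifest
) -> pd.DataFrame:
    """Group tests of every node's AUC, FDR-corrected within each metric family.

    ``auc_tables`` maps metric name -> DataFrame (rows = subjects, columns =
    1-based node indices).
    """
    rows = []
    for metric, table in auc_tables.items():
        results = []
        for node in table.columns:
            res = adjusted_group_test(
                table[node].to_dict(), manifest, unit=f"{metric}/node{node}"
            )
            results.append((node, res))
        adj = fdr_bh([r.p for _, r in results])
        for (node, r), pa in zip(results, adj):
            rows.append(
                {
                    "metric": metric,
                    "node": int(node),
                    "t": r.t,
                    "p": r.p,
                    "p_fdr": float(pa),
                    "mean_patient": r.mean_patient,
                    "mean_control": r.mean_control,
                    "direction": r.direction,
                }
            )
    return pd.DataFrame(rows)


def abnormal_node_report(tests: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Nodes significant (FDR) on any nodal metric, with direction labels.

    The returned table (node, metric, direction, p_fdr, t) is the default ROI
    hand-off to the dynamic-connectivity stage.
    """
    sig = tests.loc[tests["p_fdr"] < alpha].copy()
    if sig.empty:
        logger.info("abnormal_node_report: no node survives FDR at alpha=%g", alpha)
        return sig.reset_index(drop=True)
    return sig.sort_values(["node", "metric"]).reset_index(drop=True)
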