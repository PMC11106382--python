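"""Synthetic two-group ROI time-series cohorts with known ground truth.

Each subject's signal is band-limited (0.01-0.08 Hz at TR = 2 s by default)
correlated Gaussian noise whose N x N target correlation has a modular
(community) structure, so that binarized graphs are small-world.  Group
effects are planted by scaling correlation-target edges incident to chosen
"deficit" nodes down and "enhanced" nodes up by 1 -/+ effect_size, then
projecting back to the nearest valid correlation matrix.  On top of the
background, a small ROI subset follows a regime-switching VAR(1) whose
active directed coupling matrix is selected by a first-order Markov dwell
process; this is the hidden state structure the dynamic-connectivity stages
are expected to recover.

The signals are statistical stand-ins for preprocessed resting-state BOLD
ROI averages: no hemodynamic convolution or physiological noise is modeled.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .io_config import AtlasTable, ClinicalTable, CohortManifest, RunConfig, SubjectTimeSeries

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_cohort",
    "bandlimit",
    "sample_state_sequence",
    "default_coupling_matrices",
    "write_cohort",
]

# Default coupled subset: the six regions the causal-flow stage focuses on
# (DCG.L, SOG.R, SPG.R, ANG.R, PAL.L, STG.L in the packaged AAL-90 atlas).
DEFAULT_COUPLED_ROIS = (33, 50, 60, 66, 75, 81)
DEFAULT_DEFICIT_NODES = (33, 75, 81)   # DCG.L, PAL.L, STG.L
DEFAULT_ENHANCED_NODES = (50, 60, 66)   # SOG.R, SPG.R, ANG.R


@dataclasses.dataclass
class SimParams:
    """Cohort-level simulation parameters (defaults are the study conditions)."""

    n_patients: int = 20
    n_controls: int = 20
    T: int = 190
    n_rois: int = 90
    coupled_roi_indices: tuple[int, ...] = DEFAULT_COUPLED_ROIS  # 1-based atlas indices
    K_true: int = 2
    dwell_mean_tr: float = 100.0
    effect_size: float = 0.5
    deficit_nodes: tuple[int, ...] = DEFAULT_DEFICIT_NODES
    enhanced_nodes: tuple[int, ...] = DEFAULT_ENHANCED_NODES
    n_modules: int = 6
    r_within: float = 0.40
    r_adjacent: float = 0.15
    r_far: float = 0.03
    # Planted nodes are given atypical baseline connectivity so the group
    # effect moves their edges across the sparsity cut instead of sliding
    # along with the bulk edge distribution: deficit nodes are within-module
    # hubs (edges well above every cut in controls, well below after the
    # 1-effect_size scaling), enhanced nodes hold adjacent-module edges just
    # below the cut that the 1+effect_size scaling pushes across.
    r_deficit_hub: float = 0.66
    r_enhanced_within: float = 0.34
    r_enhanced_adjacent: float = 0.28
    coupling_matrices: tuple[np.ndarray, ...] | None = None  # default built per K_true
    plant_nhs3_correlation: bool = False
    # Upper band edge (Hz) of the coupled subset's driving noise.  Strictly
    # narrowband innovations make 22-sample lag-1 regressions ill-conditioned
    # (windows are near-sinusoidal, so lagged regressors are collinear) and
    # bias path coefficients toward zero; a wider driving band keeps the
    # planted lagged structure identifiable at the study's window length.
    coupling_innovation_high_hz: float = 0.20


@dataclasses.dataclass
class GroundTruth:
    """Planted structure: per-subject regime labels, coupling matrices, effect nodes."""

    state_sequence: dict[str, np.ndarray]  # subject_id -> length-T labels in 1..K_true
    coupling_matrices: list[np.ndarray]    # K_true directed matrices over the coupled subset
    coupled_roi_indices: tuple[int, ...]
    deficit_nodes: tuple[int, ...]
    enhanced_nodes: tuple[int, ...]
    effect_size: float

    def window_labels(self, subject_id: str, length_tr: int, step_tr: int) -> np.ndarray:
        """Majority regime label per sliding window for one subject."""
        seq = self.state_sequence[subject_id]
        T = seq.shape[0]
        n_win = (T - length_tr) // step_tr + 1
        out = np.empty(n_win, dtype=int)
        for w in range(n_win):
            chunk = seq[w * step_tr : w * step_tr + length_tr]
            vals, counts = np.unique(chunk, return_counts=True)
            out[w] = vals[np.argmax(counts)]
        return out


def bandlimit(noise: np.ndarray, low_hz: float, high_hz: float, tr_seconds: float) -> np.ndarray:
    """Zero-phase FIR band-pass applied column-wise.

    Power outside [low_hz, high_hz] is attenuated by >= 20 dB relative to the
    passband; zero-phase (forward-backward) application avoids the phase
    distortion that would bias lagged coupling estimates.
    """
    noise = np.asarray(noise, dtype=float)
    fs = 1.0 / tr_seconds
    nyq = fs / 2.0
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must lie within [0, Nyquist={nyq:g}) Hz"
        )
    T = noise.shape[0]
    numtaps = min(101, T - 2 if (T - 2) % 2 == 1 else T - 3)
    if numtaps < 9:
        raise ValueError("time series too short for band-pass filtering")
    taps = sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs)
    padlen = min(3 * numtaps, T - 1)
    return sps.filtfilt(taps, [1.0], noise, axis=0, padlen=padlen)


def sample_state_sequence(
    T: int, K_true: int, dwell_mean_tr: float, seed: int
) -> np.ndarray:
    """First-order Markov regime labels with symmetric switch probability 1/dwell."""
    if K_true < 1:
        raise ValueError("K_true must be >= 1")
    if dwell_mean_tr < 1:
        raise ValueError("dwell_mean_tr must be >= 1")
    if K_true == 1:
        return np.ones(T, dtype=int)
    rng = np.random.default_rng(seed)
    p_switch = 1.0 / dwell_mean_tr
    seq = np.empty(T, dtype=int)
    seq[0] = rng.integers(1, K_true + 1)
    for t in range(1, T):
        if rng.random() < p_switch:
            others = [k for k in range(1, K_true + 1) if k != seq[t - 1]]
            seq[t] = others[rng.integers(len(others))]
        else:
            seq[t] = seq[t - 1]
    return seq


def default_coupling_matrices(K_true: int, n: int) -> list[np.ndarray]:
    """Regime coupling matrices over an n-ROI subset (entry (i,j): influence i->j).

    The two regimes are directed rings of opposite orientation and partly
    opposite sign with identical coupling magnitudes: the clustering stage
    separates them by pattern, while the matched magnitude gives every node
    the same variance inflation in both regimes, so a subject's
    functional-connectivity structure does not depend on how long it dwells
    in either regime.  Ring magnitude 0.65 keeps the VAR stationary
    (spectral radius ~0.63) and the variance inflation modest.  Further
    regimes, if requested, are scaled copies of regime 1.
    """
    fwd = np.zeros((n, n))
    rev = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        fwd[i, j] = 0.65 if i % 2 == 0 else -0.611
        rev[j, i] = -0.65 if i % 2 == 0 else 0.611
    mats = [fwd, rev]
    while len(mats) < K_true:
        mats.append(fwd * (0.3 / len(mats)))
    return mats[:K_true]


def _nearest_correlation(C: np.ndarray, n_iter: int = 5, floor: float = 1e-6) -> np.ndarray:
    """Project to a valid correlation matrix by eigenvalue clipping + renormalization."""
    C = (C + C.T) / 2.0
    for _ in range(n_iter):
        w, V = np.linalg.eigh(C)
        if w.min() >= floor:
            break
        C = (V * np.maximum(w, floor)) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C


def _background_target(p: SimParams) -> np.ndarray:
    """Modular correlation target: blocks on a ring with weak long-range links."""
    N = p.n_rois
    module = np.arange(N) * p.n_modules // N  # contiguous blocks
    C = np.full((N, N), p.r_far)
    ring = (np.abs(module[:, None] - module[None, :]) % p.n_modules)
    adjacent = (ring == 1) | (ring == p.n_modules - 1)
    C[adjacent] = p.r_adjacent
    C[module[:, None] == module[None, :]] = p.r_within
    for idx in p.deficit_nodes:
        i = idx - 1
        same = module == module[i]
        C[i, same] = C[same, i] = p.r_deficit_hub
    for idx in p.enhanced_nodes:
        i = idx - 1
        same = module == module[i]
        C[i, same] = C[same, i] = p.r_enhanced_within
        adj_i = adjacent[i]
        C[i, adj_i] = C[adj_i, i] = p.r_enhanced_adjacent
    np.fill_diagonal(C, 1.0)
    return _nearest_correlation(C)


def _group_target(base: np.ndarray, p: SimParams, severity: float = 1.0) -> np.ndarray:
    """Scale edges incident to planted nodes by 1 -/+ effect_size*severity."""
    C = base.copy()
    scale = np.ones(C.shape[0])
    for idx in p.deficit_nodes:
        scale[idx - 1] *= max(0.0, 1.0 - p.effect_size * severity)
    for idx in p.enhanced_nodes:
        scale[idx - 1] *= 1.0 + p.effect_size * severity
    mask = ~np.eye(C.shape[0], dtype=bool)
    C = np.where(mask, C * np.outer(scale, scale), C)
    # an edge touching two planted nodes picks up both factors; clip then project
    C = np.clip(C, -0.99, 0.99)
    np.fill_diagonal(C, 1.0)
    C = _nearest_correlation(C)
    if np.linalg.eigvalsh(C).min() <= 0:
        raise ValueError("effect size produced a non-positive-definite correlation target")
    return C


def _sqrt_psd(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    return (V * np.sqrt(np.maximum(w, 0.0))) @ V.T


def _check_stationary(mats: list[np.ndarray]) -> None:
    for k, A in enumerate(mats, start=1):
        rad = np.abs(np.linalg.eigvals(A.T)).max()
        if rad >= 1.0:
            raise ValueError(
                f"coupling matrix for regime {k} is non-stationary (spectral radius {rad:.3f} >= 1)"
            )


def simulate_cohort(
    config: RunConfig, sim_params: SimParams, seed: int
) -> tuple[list[SubjectTimeSeries], GroundTruth, CohortManifest, ClinicalTable]:
    """Simulate the full two-group cohort.

    Identical (config, sim_params, seed) gives a bit-identical cohort.
    """
    p = sim_params
    if p.coupled_roi_indices and max(p.coupled_roi_indices) > p.n_rois:
        raise ValueError("coupled ROI index exceeds n_rois")
    if p.T < config.window_length_tr:
        raise ValueError("T must be at least the sliding-window length")
    if p.K_true >= 1 and p.dwell_mean_tr < 2:
        raise ValueError("dwell_mean_tr must be >= 2")

    n_sub = p.coupled_roi_indices and len(p.coupled_roi_indices) or 0
    if p.coupling_matrices is not None:
        coupling = [np.asarray(A, dtype=float) for A in p.coupling_matrices]
    elif n_sub:
        coupling = default_coupling_matrices(p.K_true, n_sub)
    else:
        coupling = []
    for A in coupling:
        if np.any(np.diag(A) != 0):
            raise ValueError("coupling matrices must have a zero diagonal")
    _check_stationary(coupling)

    rng = np.random.default_rng(seed)
    base = _background_target(p)
    control_root = _sqrt_psd(base)

    subjects: list[SubjectTimeSeries] = []
    state_sequences: dict[str, np.ndarray] = {}
    manifest_rows = []
    clinical_rows = []
    sub_idx = np.asarray(p.coupled_roi_indices, dtype=int) - 1

    roster = [("patient", i + 1) for i in range(p.n_patients)] + [
        ("control", i + 1) for i in range(p.n_controls)
    ]
    for group, num in roster:
        sid = f"{'jme' if group == 'patient' else 'hc'}{num:03d}"
        age = float(np.round(np.clip(rng.normal(20.5, 6.0), 12, 45), 1))
        sex = "M" if rng.random() < 0.5 else "F"
        severity = 1.0
        if group == "patient":
            sev_u = float(rng.uniform(0.5, 1.5)) if p.plant_nhs3_correlation else 1.0
            severity = sev_u
            target = _group_target(base, p, severity=severity) if p.effect_size else base
            root = _sqrt_psd(target)
            nhs3 = (
                float(np.round(np.clip(15 * (sev_u - 0.5) + rng.normal(0, 1.0), 0, 15), 1))
                if p.plant_nhs3_correlation
                else float(np.round(rng.uniform(0, 15), 1))
            )
            duration = float(np.round(max(1.0, rng.normal(49.0, 47.0)), 0))
            clinical_rows.append((sid, duration, nhs3))
        else:
            root = control_root

        white = rng.standard_normal((p.T, p.n_rois))
        corr_noise = white @ root.T
        bg = bandlimit(corr_noise, config.bandpass_low_hz, config.bandpass_high_hz, config.tr_seconds)
        sd = bg.std(axis=0)
        bg = bg / np.where(sd > 0, sd, 1.0)
        if n_sub:
            # wider-band innovations for the coupled subset (see SimParams)
            hi = min(p.coupling_innovation_high_hz, 0.499 / config.tr_seconds)
            drv = bandlimit(corr_noise[:, sub_idx], config.bandpass_low_hz, hi, config.tr_seconds)
            dsd = drv.std(axis=0)
            drv = drv / np.where(dsd > 0, dsd, 1.0)

        seq = sample_state_sequence(
            p.T, p.K_true, p.dwell_mean_tr, seed=int(rng.integers(2**31))
        )
        data = bg
        if n_sub and any(np.any(A) for A in coupling):
            # coupled subset: VAR recursion driven by its in-band background
            x = np.zeros((p.T, n_sub))
            x[0] = drv[0]
            for t in range(1, p.T):
                A = coupling[seq[t] - 1]
                x[t] = A.T @ x[t - 1] + drv[t]
            data = bg.copy()
            data[:, sub_idx] = x

        subjects.append(
            SubjectTimeSeries(
                data=data,
                subject_id=sid,
                tr_seconds=config.tr_seconds,
                group=group,
                age=age,
                sex=sex,
            )
        )
        state_sequences[sid] = seq
        manifest_rows.append((sid, group, age, sex))

    import pandas as pd

    manifest = CohortManifest(
        pd.DataFrame(manifest_rows, columns=["subject_id", "group", "age", "sex"])
    )
    clinical = ClinicalTable(
        pd.DataFrame(clinical_rows, columns=["subject_id", "duration_months", "nhs3"])
    )
    truth = GroundTruth(
        state_sequence=state_sequences,
        coupling_matrices=coupling,
        coupled_roi_indices=tuple(p.coupled_roi_indices),
        deficit_nodes=tuple(p.deficit_nodes),
        enhanced_nodes=tuple(p.enhanced_nodes),
        effect_size=p.effect_size,
    )
    return subjects, truth, manifest, clinical


def write_cohort(
    out_dir: str | Path,
    subjects: list[SubjectTimeSeries],
    truth: GroundTruth,
    manifest: CohortManifest,
    clinical: ClinicalTable,
    atlas: AtlasTable,
) -> None:
    """Write one TSV per subject plus manifest, clinical and ground-truth files."""
    from .io_config import write_timeseries

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts in subjects:
        write_timeseries(ts, out / f"{ts.subject_id}.tsv", atlas)
    manifest.to_tsv(out / "manifest.tsv")
    clinical.to_tsv(out / "clinical.tsv")
    payload = {
        "coupled_roi_indices": list(truth.coupled_roi_indices),
        "deficit_nodes": list(truth.deficit_nodes),
        "enhanced_nodes": list(truth.enhanced_nodes),
        "effect_size": truth.effect_size,
        "coupling_matrices": [A.tolist() for A in truth.coupling_matrices],
        "state_sequence": {k: v.tolist() for k, v in truth.state_sequence.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(payload))
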