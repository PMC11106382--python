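"""File formats and run configuration.

Everything the pipeline reads or writes is plain delimited text
(tab-separated, ``.`` decimal, UTF-8): ROI time series as T x N TSV with a
header of ROI abbreviations, square matrices as headerless N x N TSV with a
JSON sidecar naming the row/column labels, and the cohort manifest /
clinical tables as TSV with named columns.  All node indices exposed here
are 1-based, following the AAL atlas convention.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AtlasTable",
    "CohortManifest",
    "ClinicalTable",
    "RunConfig",
    "SubjectTimeSeries",
    "default_atlas",
    "load_config",
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "read_manifest",
    "read_clinical",
]


@dataclasses.dataclass(frozen=True)
class AtlasTable:
    """Ordered parcellation label table: (1-based index, abbreviation, hemisphere)."""

    entries: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        idx = [e[0] for e in self.entries]
        abbr = [e[1] for e in self.entries]
        if len(self.entries) < 2:
            raise ValueError("atlas must contain more than one node")
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("atlas indices must be consecutive 1..N")
        if len(set(abbr)) != len(abbr):
            raise ValueError("atlas abbreviations must be unique")
        for e in self.entries:
            if e[2] not in ("L", "R"):
                raise ValueError(f"hemisphere flag must be L or R, got {e[2]!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.entries)

    @property
    def abbreviations(self) -> list[str]:
        return [e[1] for e in self.entries]

    def index_of(self, abbreviation: str) -> int:
        """1-based atlas index of an abbreviation."""
        for i, a, _ in self.entries:
            if a == abbreviation:
                return i
        raise KeyError(abbreviation)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AtlasTable":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(zip(df["index"].astype(int), df["abbreviation"], df["hemisphere"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, columns=["index", "abbreviation", "hemisphere"]).to_csv(
            path, sep="\t", index=False
        )


def default_atlas() -> AtlasTable:
    """The packaged 90-region AAL cortical/subcortical label table."""
    with resources.files("fcdec.data").joinpath("aal90.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    return AtlasTable(tuple(zip(df["index"].astype(int), df["abbreviation"], df["hemisphere"])))


@dataclasses.dataclass
class SubjectTimeSeries:
    """One subject's T x N ROI signal matrix with group/covariate metadata."""

    data: np.ndarray  # shape (T, N)
    subject_id: str
    tr_seconds: float = 2.0
    group: str | None = None  # "patient" | "control"
    age: float | None = None
    sex: str | None = None  # "M" | "F"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("time series must be a T x N matrix with T >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in time series of {self.subject_id}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass(frozen=True)
class CohortManifest:
    """Subject-level roster: id, group (patient/control), age, sex."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "age", "sex"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        if self.frame["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in manifest")
        bad = set(self.frame["group"]) - {"patient", "control"}
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame["subject_id"])

    def group_of(self, subject_id: str) -> str:
        return str(self.frame.set_index("subject_id").loc[subject_id, "group"])

    def ids_in_group(self, group: str) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == group, "subject_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass(frozen=True)
class ClinicalTable:
    """Patient clinical variables: epilepsy duration (months) and NHS3 severity score."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "duration_months", "nhs3"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"clinical table missing columns {sorted(missing)}")
        if (self.frame["duration_months"] < 0).any() or (self.frame["nhs3"] < 0).any():
            raise ValueError("clinical values must be non-negative")

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> CohortManifest:
    return CohortManifest(pd.read_csv(path, sep="\t"))


def read_clinical(path: str | Path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, sep="\t"))


@dataclasses.dataclass
class RunConfig:
    """Run parameters with the study defaults.

    Sparsity grid 0.10-0.34 in steps of 0.01; sliding window of 22 TR with a
    1 TR step at TR = 2 s (44 s windows); VAR order p = 1; candidate state
    counts 2..10; 100 degree-preserving null networks; alpha = 0.05; the
    synthetic generator's passband 0.01-0.08 Hz.
    """

    sparsity_min: float = 0.10
    sparsity_max: float = 0.34
    sparsity_step: float = 0.01
    window_length_tr: int = 22
    window_step_tr: int = 1
    tr_seconds: float = 2.0
    var_order: int = 1
    k_min: int = 2
    k_max: int = 10
    n_null_networks: int = 100
    rng_seed: int = 0
    alpha: float = 0.05
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.08

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.sparsity_min < self.sparsity_max < 1):
            raise ValueError(
                "sparsity bounds invalid: require 0 < sparsity_min < sparsity_max < 1 "
                f"(got sparsity_min={self.sparsity_min}, sparsity_max={self.sparsity_max})"
            )
        if self.sparsity_step <= 0:
            raise ValueError(f"sparsity_step must be positive (got {self.sparsity_step})")
        if self.window_length_tr < self.var_order + 2:
            raise ValueError(
                f"window_length_tr must be >= var_order + 2 (got window_length_tr={self.window_length_tr})"
            )
        if self.window_step_tr < 1:
            raise ValueError(f"window_step_tr must be a positive integer (got {self.window_step_tr})")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive (got {self.tr_seconds})")
        if self.var_order < 1:
            raise ValueError(f"var_order must be a positive integer (got {self.var_order})")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError(f"k range invalid: k_min={self.k_min}, k_max={self.k_max}")
        if self.n_null_networks < 1:
            raise ValueError(f"n_null_networks must be positive (got {self.n_null_networks})")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1) (got {self.alpha})")
        if not (self.bandpass_low_hz < self.bandpass_high_hz):
            raise ValueError(
                "bandpass band invalid: require bandpass_low_hz < bandpass_high_hz "
                f"(got {self.bandpass_low_hz}, {self.bandpass_high_hz})"
            )

    @property
    def window_duration_seconds(self) -> float:
        return self.window_length_tr * self.tr_seconds

    @property
    def sparsity_grid(self) -> np.ndarray:
        """The candidate sparsity grid, inclusive of both ends."""
        n = int(round((self.sparsity_max - self.sparsity_min) / self.sparsity_step)) + 1
        return np.round(self.sparsity_min + self.sparsity_step * np.arange(n), 10)

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config; absent keys fall back to the study defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def read_timeseries(path: str | Path, atlas: AtlasTable, **meta) -> SubjectTimeSeries:
    """Read a subject's T x N TSV, re-ordering columns to atlas order.

    The header row must contain exactly the atlas abbreviations (any order).
    """
    df = pd.read_csv(path, sep="\t")
    want = atlas.abbreviations
    have = list(df.columns)
    if sorted(have) != sorted(want):
        raise ValueError(
            f"{path}: columns do not match atlas ({len(have)} columns vs {len(want)} atlas nodes)"
        )
    df = df[want]
    data = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-numeric or non-finite cell in time series")
    meta.setdefault("subject_id", Path(path).stem)
    return SubjectTimeSeries(data=data, **meta)


def write_timeseries(ts: SubjectTimeSeries, path: str | Path, atlas: AtlasTable) -> None:
    pd.DataFrame(ts.data, columns=atlas.abbreviations).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def write_matrix(
    matrix: np.ndarray,
    path: str | Path,
    labels: Sequence[str] | None = None,
    kind: str | None = None,
) -> None:
    """Write a matrix as headerless TSV (17 significant digits) with a JSON sidecar."""
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite entries")
    np.savetxt(path, matrix, delimiter="\t", fmt="%.17g")
    if labels is not None or kind is not None:
        sidecar = {"labels": list(labels) if labels is not None else None, "kind": kind}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a headerless TSV matrix; ragged rows raise."""
    mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    return mat
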