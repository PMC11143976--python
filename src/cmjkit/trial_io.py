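"""Reading and writing force-plate trials and study manifests.

Canonical internal units are newtons and seconds.  Samples are 0-indexed and
the time of sample ``i`` is ``i / sampling_rate``.  Trial files are delimited
text with either a single force column or ``time, force`` columns; a
:class:`Dialect` describes delimiter, header, units and time-column presence.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CONDITIONS, GRAVITY
from .errors import (
    EmptyTrialError,
    NonNumericDataError,
    NonUniformSamplingError,
    SubjectNotStillError,
)

__all__ = [
    "Dialect",
    "ForceTrial",
    "BodyWeight",
    "read_force_trial",
    "write_force_trial",
    "compute_body_weight",
    "read_manifest",
    "write_manifest",
]


@dataclass(frozen=True)
class Dialect:
    """How a delimited trial file is laid out.

    Parameters
    ----------
    delimiter : field separator, ``","`` or ``"\\t"``.
    has_header : whether the first row is column names.
    force_unit : ``"N"`` or ``"kN"``; converted to newtons on read.
    has_time_column : if True the first column is time in seconds and the
        sampling rate is inferred from it; otherwise ``sampling_rate`` is used.
    sampling_rate : fallback rate in Hz when no time column is present.
    """

    delimiter: str = ","
    has_header: bool = True
    force_unit: str = "N"
    has_time_column: bool = True
    sampling_rate: float = 1000.0


@dataclass
class ForceTrial:
    """One CMJ trial: uniformly sampled vertical GRF plus identifiers."""

    force: np.ndarray  # N, one sample per row
    sampling_rate: float  # Hz
    body_mass: float | None = None  # kg; may be derived from quiet standing
    participant_id: str = ""
    condition: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if self.force.ndim != 1 or self.force.size == 0:
            raise EmptyTrialError("force trace must be a non-empty 1D array")
        if not np.all(np.isfinite(self.force)):
            raise NonNumericDataError("force trace contains NaN/inf")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.force.size)

    @property
    def time(self) -> np.ndarray:
        """Time of each sample in seconds (sample i at i/rate)."""
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate


@dataclass(frozen=True)
class BodyWeight:
    """Body weight estimated from quiet standing."""

    body_weight_N: float
    body_mass_kg: float
    quiet_sd_N: float  # force SD in the weighing window, used for onset detection


_UNIT_TO_N = {"N": 1.0, "kN": 1000.0}

#: Relative tolerance on timestamp spacing before a file is rejected as
#: non-uniformly sampled.
TIME_JITTER_TOL = 1e-3


def read_force_trial(
    path: str | Path | _io.IOBase,
    dialect: Dialect = Dialect(),
    *,
    participant_id: str = "",
    condition: str = "",
    trial_index: int = 0,
    body_mass: float | None = None,
) -> ForceTrial:
    """Read one trial file into a validated :class:`ForceTrial`.

    Raises
    ------
    EmptyTrialError, NonNumericDataError, NonUniformSamplingError
    """
    try:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            header=0 if dialect.has_header else None,
            comment="#",
        )
    except pd.errors.EmptyDataError as exc:
        raise EmptyTrialError(f"empty trial file: {path}") from exc
    if df.shape[0] == 0:
        raise EmptyTrialError(f"trial file has no data rows: {path}")

    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        raise NonNumericDataError(f"non-numeric rows in trial file: {path}")

    scale = _UNIT_TO_N[dialect.force_unit]
    if dialect.has_time_column:
        if df.shape[1] < 2:
            raise NonNumericDataError("dialect expects time + force columns")
        t = df.iloc[:, 0].to_numpy(float)
        force = df.iloc[:, 1].to_numpy(float) * scale
        dts = np.diff(t)
        if dts.size == 0:
            raise EmptyTrialError("trial has a single sample")
        dt = np.median(dts)
        if dt <= 0 or np.any(np.abs(dts - dt) > TIME_JITTER_TOL * dt):
            raise NonUniformSamplingError(
                f"timestamps deviate from uniform grid by >{TIME_JITTER_TOL:.1%}"
            )
        rate = 1.0 / dt
    else:
        force = df.iloc[:, 0].to_numpy(float) * scale
        rate = dialect.sampling_rate

    return ForceTrial(
        force=force,
        sampling_rate=rate,
        body_mass=body_mass,
        participant_id=participant_id,
        condition=condition,
        trial_index=trial_index,
    )


def write_force_trial(
    trial: ForceTrial, path: str | Path, dialect: Dialect = Dialect()
) -> None:
    """Write a trial as delimited text (inverse of :func:`read_force_trial`)."""
    scale = _UNIT_TO_N[dialect.force_unit]
    cols = {}
    if dialect.has_time_column:
        cols["time_s"] = trial.time
    cols[f"fz_{dialect.force_unit}"] = trial.force / scale
    df = pd.DataFrame(cols)
    df.to_csv(
        path,
        sep=dialect.delimiter,
        index=False,
        header=dialect.has_header,
        float_format="%.12g",
    )


def compute_body_weight(
    trial: ForceTrial,
    weighing_window: float = 1.0,
    *,
    g: float = GRAVITY,
    stillness_ceiling: float = 0.03,
) -> BodyWeight:
    """Estimate body weight as the mean force over a quiet-standing window.

    The window is the first ``weighing_window`` seconds of the record, which
    must lie within quiet standing.  The window force SD is returned for onset
    thresholding downstream.

    Raises
    ------
    SubjectNotStillError
        If the window SD exceeds ``stillness_ceiling`` (default 3%) of the
        window mean — the subject moved during weighing.
    """
    n = int(round(weighing_window * trial.sampling_rate))
    n = max(2, min(n, trial.n_samples))
    window = trial.force[:n]
    bw = float(np.mean(window))
    sd = float(np.std(window, ddof=1))
    if bw <= 0:
        raise SubjectNotStillError("non-positive mean force in weighing window")
    if sd > stillness_ceiling * bw:
        raise SubjectNotStillError(
            f"weighing-window force SD {sd:.1f} N exceeds "
            f"{stillness_ceiling:.0%} of mean {bw:.1f} N — subject not still"
        )
    return BodyWeight(body_weight_N=bw, body_mass_kg=bw / g, quiet_sd_N=sd)


MANIFEST_COLUMNS = ["participant", "condition", "trial", "body_mass", "rpe", "file"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a study manifest CSV (participant, condition, trial, body_mass,
    rpe, file) and validate condition labels and per-cell trial counts."""
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(
            f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}"
        )
    rpe = df["rpe"].dropna()
    if len(rpe) and ((rpe < 6) | (rpe > 20)).any():
        raise ValueError("RPE values must lie on the Borg 6-20 scale")
    return df[MANIFEST_COLUMNS]


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, index=False)
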