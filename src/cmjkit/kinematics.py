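"""Phase segmentation and numerical integration of CMJ force traces.

The jump is divided at four instants (movement onset, minimum
center-of-mass velocity, end of braking, take-off) into an eccentric phase
(onset -> end of braking, where downward COM velocity returns to zero) and a
concentric phase (end of braking -> take-off).  Velocity, displacement and
power are derived from the vertical GRF via the impulse-momentum theorem:
``a = F/m - g``, integrated with the trapezoidal rule from onset with
``v(onset) = 0``.  No filtering is applied by default so that impulse is
preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import GRAVITY
from .errors import NoCountermovementError, NoFlightError, NoMovementError
from .trial_io import ForceTrial

__all__ = [
    "KinematicSeries",
    "PhaseSegmentation",
    "detect_onset",
    "detect_takeoff",
    "integrate_motion",
    "segment_phases",
]


@dataclass
class KinematicSeries:
    """Per-sample kinematics aligned with a trial's force samples.

    ``power`` is total vertical GRF power per unit mass, ``(F/m) * v`` in
    W/kg — the convention whose concentric peak matches the familiar
    60-70 W/kg scale.  Net-force power ``(F/m - g) * v`` is available via
    :func:`integrate_motion` with ``power_convention="net"``.
    """

    net_acceleration: np.ndarray  # m/s^2, F/m - g
    velocity: np.ndarray  # m/s, 0 before onset
    displacement: np.ndarray  # m
    power: np.ndarray  # W/kg
    sampling_rate: float
    onset_index: int

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.velocity.size) / self.sampling_rate


@dataclass(frozen=True)
class PhaseSegmentation:
    """Indices of the phase-division instants.

    Invariant: ``onset < min_velocity < end_of_braking <= takeoff``.  The
    eccentric window is ``[onset, end_of_braking]``, the concentric window
    ``[end_of_braking, takeoff]``.
    """

    onset_index: int
    min_velocity_index: int
    end_of_braking_index: int
    takeoff_index: int

    def __post_init__(self) -> None:
        ok = (
            self.onset_index
            < self.min_velocity_index
            < self.end_of_braking_index
            <= self.takeoff_index
        )
        if not ok:
            raise NoCountermovementError(
                "phase instants out of order: "
                f"onset={self.onset_index}, vmin={self.min_velocity_index}, "
                f"eob={self.end_of_braking_index}, takeoff={self.takeoff_index}"
            )

    def eccentric_duration(self, rate: float) -> float:
        return (self.end_of_braking_index - self.onset_index) / rate

    def concentric_duration(self, rate: float) -> float:
        return (self.takeoff_index - self.end_of_braking_index) / rate


def detect_onset(
    trial: ForceTrial,
    body_weight_N: float,
    quiet_sd_N: float,
    *,
    k: float = 5.0,
    search_start: int = 0,
) -> int:
    """Detect movement onset from the force trace.

    The first sample where ``|F - BW|`` exceeds ``k * quiet_sd`` marks
    unambiguous movement; the onset is then backtracked to the first sample
    after the trace last sat inside the quiet-standing noise band
    (``|F - BW| <= quiet_sd``) — for a step input this is the step edge.

    Raises
    ------
    NoMovementError if the threshold is never crossed.
    """
    dev = np.abs(trial.force - body_weight_N)
    crossings = np.flatnonzero(dev[search_start:] > k * quiet_sd_N)
    if crossings.size == 0:
        raise NoMovementError("no movement detected: onset threshold never crossed")
    first = search_start + int(crossings[0])
    quiet = np.flatnonzero(dev[: first + 1] <= quiet_sd_N)
    return min(int(quiet[-1]) + 1, first) if quiet.size else first


def detect_takeoff(
    trial: ForceTrial,
    onset_index: int = 0,
    *,
    threshold_N: float = 10.0,
    min_flight_duration: float = 0.010,
) -> int:
    """First sample after onset where force stays below ``threshold_N`` for at
    least ``min_flight_duration`` — the start of flight.

    "Stays below" is assessed on the mean force over the following
    ``min_flight_duration`` window, so isolated noise samples poking above
    the threshold do not postpone the detected take-off.

    Raises
    ------
    NoFlightError if no sustained sub-threshold run exists.
    """
    w = max(1, int(round(min_flight_duration * trial.sampling_rate)))
    f = trial.force[onset_index:]
    if f.size >= w:
        csum = np.concatenate(([0.0], np.cumsum(f)))
        window_means = (csum[w:] - csum[:-w]) / w
        hits = np.flatnonzero((window_means < threshold_N) & (f[: window_means.size] < threshold_N))
        if hits.size:
            return onset_index + int(hits[0])
    raise NoFlightError("no flight detected (trial truncated before take-off?)")


def integrate_motion(
    trial: ForceTrial,
    body_mass: float,
    onset_index: int,
    *,
    g: float = GRAVITY,
    power_convention: str = "total",
) -> KinematicSeries:
    """Derive net acceleration, velocity, displacement and mass-normalized
    power from the force trace by trapezoidal integration from onset.

    Samples before onset carry zero velocity and displacement.
    """
    fm = trial.force / body_mass
    a = fm - g
    n = trial.n_samples
    dt = trial.dt
    v = np.zeros(n)
    s = np.zeros(n)
    seg = a[onset_index:]
    v[onset_index:] = np.concatenate(
        ([0.0], np.cumsum(0.5 * (seg[1:] + seg[:-1]) * dt))
    )
    vseg = v[onset_index:]
    s[onset_index:] = np.concatenate(
        ([0.0], np.cumsum(0.5 * (vseg[1:] + vseg[:-1]) * dt))
    )
    if power_convention == "total":
        p = fm * v
    elif power_convention == "net":
        p = a * v
    else:
        raise ValueError("power_convention must be 'total' or 'net'")
    return KinematicSeries(
        net_acceleration=a,
        velocity=v,
        displacement=s,
        power=p,
        sampling_rate=trial.sampling_rate,
        onset_index=onset_index,
    )


def segment_phases(
    kin: KinematicSeries, onset_index: int, takeoff_index: int
) -> PhaseSegmentation:
    """Locate minimum velocity and end of braking between onset and take-off.

    End of braking is the first upward zero crossing of velocity after the
    minimum, snapped to the first non-negative sample (the "later" side of the
    interpolated crossing).

    Raises
    ------
    NoCountermovementError if velocity has no negative minimum or never
    crosses zero upward before take-off (aborted jump).
    """
    v = kin.velocity
    if takeoff_index <= onset_index + 2:
        raise NoCountermovementError("window too short to segment")
    win = v[onset_index : takeoff_index + 1]
    i_min = onset_index + int(np.argmin(win))
    if v[i_min] >= 0 or i_min == onset_index:
        raise NoCountermovementError(
            "no countermovement: velocity has no negative minimum"
        )
    after = v[i_min : takeoff_index + 1]
    pos = np.flatnonzero(after >= -1e-12)  # tolerate exact-zero crossings
    if pos.size == 0:
        raise NoCountermovementError(
            "aborted jump: velocity never returns to zero before take-off"
        )
    eob = i_min + int(pos[0])
    return PhaseSegmentation(
        onset_index=onset_index,
        min_velocity_index=i_min,
        end_of_braking_index=eob,
        takeoff_index=takeoff_index,
    )
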