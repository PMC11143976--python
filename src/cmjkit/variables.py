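"""Per-trial CMJ variables, trial averaging and percent changes.

All force, impulse and power quantities are normalized to body mass.  The
variable set follows standard CMJ monitoring practice:

========  ======  =====================================================
JH        cm      jump height from peak concentric velocity, v^2 / (2g)
PF        N/kg    peak mass-normalized force, onset -> take-off
PP        W/kg    peak mass-normalized power, onset -> take-off
EccI      Ns/kg   braking net impulse (min velocity -> end of braking);
                  equals |v_min| by impulse-momentum
ConI      Ns/kg   concentric net impulse (end of braking -> take-off);
                  equals take-off velocity by impulse-momentum
EccMP     W/kg    mean |power| over the eccentric phase
ConMP     W/kg    mean power over the concentric phase
EccDur    s       eccentric-phase duration
ConDur    s       concentric-phase duration
ED:CD     --      duration ratio ConDur / EccDur (rises under fatigue:
                  relatively longer concentric phase)
========  ======  =====================================================

Notes on the two eccentric conventions: the *net* impulse over the whole
eccentric phase is identically zero (velocity starts and ends the phase at
zero), so EccI is defined over the braking portion only, where it equals the
magnitude of the peak downward velocity.  COM power is negative during the
descent, so EccMP is reported as a magnitude; set ``eccentric_power_signed``
to get the signed mean instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .constants import GRAVITY
from .kinematics import KinematicSeries, PhaseSegmentation
from .trial_io import ForceTrial

__all__ = [
    "CmjVariables",
    "SessionSummary",
    "compute_variables",
    "average_trials",
    "percent_change",
    "VARIABLE_NAMES",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CmjVariables:
    jump_height_cm: float
    peak_force: float  # N/kg
    peak_power: float  # W/kg
    eccentric_impulse: float  # Ns/kg
    concentric_impulse: float  # Ns/kg
    eccentric_mean_power: float  # W/kg
    concentric_mean_power: float  # W/kg
    eccentric_duration: float  # s
    concentric_duration: float  # s
    duration_ratio: float  # ConDur / EccDur
    takeoff_velocity: float = float("nan")  # m/s, kept for diagnostics
    jump_height_takeoff_cm: float = float("nan")  # JH from take-off velocity
    flight_height_cm: float = float("nan")  # g t_f^2 / 8, when landing present


#: Presentation order matching the standard monitoring table.
VARIABLE_NAMES = [
    "jump_height_cm",
    "peak_force",
    "peak_power",
    "eccentric_impulse",
    "concentric_impulse",
    "eccentric_mean_power",
    "concentric_mean_power",
    "eccentric_duration",
    "concentric_duration",
    "duration_ratio",
]


@dataclass(frozen=True)
class SessionSummary:
    """Trial-averaged variables for one participant x condition."""

    participant: str
    condition: str
    variables: CmjVariables
    rpe: float | None = None  # Borg 6-20
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.rpe is not None and not (6 <= self.rpe <= 20):
            raise ValueError("RPE must lie on the Borg 6-20 scale")


def _trapz(y: np.ndarray, dx: float) -> float:
    return float(np.trapezoid(y, dx=dx))


def compute_variables(
    trial: ForceTrial,
    kin: KinematicSeries,
    seg: PhaseSegmentation,
    *,
    g: float = GRAVITY,
    jump_height_from: str = "peak",
    eccentric_power_signed: bool = False,
) -> CmjVariables:
    """Compute the per-trial variable set from segmented kinematics.

    ``jump_height_from`` selects the velocity used for JH: ``"peak"`` (maximum
    concentric velocity, the default) or ``"takeoff"``.
    """
    on, vmin, eob, to = (
        seg.onset_index,
        seg.min_velocity_index,
        seg.end_of_braking_index,
        seg.takeoff_index,
    )
    dt = 1.0 / kin.sampling_rate
    fm = kin.net_acceleration + g  # F/m
    v = kin.velocity
    p = kin.power

    v_takeoff = float(v[to])
    v_peak = float(np.max(v[on : to + 1]))
    jh_peak = v_peak**2 / (2 * g) * 100.0
    jh_takeoff = v_takeoff**2 / (2 * g) * 100.0

    ecc_power = p[on : eob + 1]
    ecc_mp = float(np.mean(ecc_power if eccentric_power_signed else np.abs(ecc_power)))

    # flight height from flight time when a landing is present in the record
    flight_cm = float("nan")
    landing = np.flatnonzero(trial.force[to:] > 30.0)
    if landing.size:
        t_flight = landing[0] * dt
        flight_cm = g * t_flight**2 / 8.0 * 100.0

    ecc_dur = seg.eccentric_duration(kin.sampling_rate)
    con_dur = seg.concentric_duration(kin.sampling_rate)
    return CmjVariables(
        jump_height_cm=jh_peak if jump_height_from == "peak" else jh_takeoff,
        peak_force=float(np.max(fm[on : to + 1])),
        peak_power=float(np.max(p[on : to + 1])),
        # net impulses evaluated with the interpolated phase boundary, where
        # v = 0 by definition: braking impulse = |v_min|, concentric = v_to
        eccentric_impulse=float(-v[vmin]),
        concentric_impulse=v_takeoff,
        eccentric_mean_power=ecc_mp,
        concentric_mean_power=float(np.mean(p[eob : to + 1])),
        eccentric_duration=ecc_dur,
        concentric_duration=con_dur,
        duration_ratio=con_dur / ecc_dur,
        takeoff_velocity=v_takeoff,
        jump_height_takeoff_cm=jh_takeoff,
        flight_height_cm=flight_cm,
    )


def average_trials(
    trials: list[CmjVariables],
    *,
    participant: str = "",
    condition: str = "",
    rpe: float | None = None,
) -> SessionSummary:
    """Arithmetic mean of each variable over the available trials of one
    participant x session (three trials in the standard protocol)."""
    if not trials:
        raise ValueError("no trials to average")
    if len(trials) == 1:
        logger.warning(
            "averaging a single trial for %s/%s", participant, condition
        )
    means = {
        f.name: float(np.mean([getattr(t, f.name) for t in trials]))
        for f in fields(CmjVariables)
    }
    return SessionSummary(
        participant=participant,
        condition=condition,
        variables=CmjVariables(**means),
        rpe=rpe,
        n_trials=len(trials),
    )


def percent_change(baseline_value: float, other_value: float) -> float:
    """Signed percent change of ``other`` relative to ``baseline``:
    ``100 * (other - baseline) / baseline``.  "X% lower" corresponds to -X.

    Full precision is returned; presentation layers round to one decimal.
    """
    if baseline_value == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    return 100.0 * (other_value - baseline_value) / baseline_value
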